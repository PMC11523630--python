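"""Unit and property tests for the core model functions."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spathe import (
    ModelParameters,
    SystemState,
    VisitProbabilities,
    full_derivatives,
    mating_success,
    persistence_boundary_r,
    persistence_index,
    plant_only_derivatives,
    pollination_success,
    visit_probabilities,
    visit_stats_closed_form,
    visit_stats_combinatorial,
)

# ---------------------------------------------------------------------------
# parameters and state containers
# ---------------------------------------------------------------------------


def test_default_parameters_match_reference_table(defaults):
    """The fixed life-history defaults are the calibrated reference values."""
    assert defaults.r_P == 1.0
    assert defaults.K_X == defaults.K_Y == 15.0
    assert defaults.g_JM == 0.05
    assert defaults.g_FM == 0.01
    assert defaults.d_J == 0.015
    assert defaults.d_M == defaults.d_F == 0.01
    assert defaults.s == 0.5
    assert defaults.f == 2.0
    assert defaults.d_Y == 0.1
    assert defaults.A_X == 1.0
    assert defaults.A_Y == 10.0
    assert defaults.q == 0.5
    assert defaults.N == 10


@pytest.mark.parametrize(
    "overrides",
    [
        {"a_M": -0.1},
        {"K_X": 0.0},
        {"s": 1.5},
        {"N": 0},
        {"N": 2.5},
        {"d_Y": float("nan")},
    ],
)
def test_parameter_validation_rejects_bad_values(overrides):
    with pytest.raises((ValueError, TypeError)):
        ModelParameters(**overrides)


def test_parameters_json_round_trip_is_lossless(tmp_path, defaults):
    p = defaults.replace(a_M=0.123456789012345, g_MF=0.0275, N=17)
    path = tmp_path / "params.json"
    p.to_json(path)
    assert ModelParameters.from_json(path) == p
    assert ModelParameters.from_json(p.to_json()) == p


def test_parameters_from_dict_rejects_unknown_keys():
    with pytest.raises(ValueError, match="unknown parameter"):
        ModelParameters.from_dict({"a_M": 0.4, "bogus": 1.0})


def test_state_rejects_negative_or_nonfinite():
    with pytest.raises(ValueError):
        SystemState(-1.0, 0, 0, 0, 0)
    with pytest.raises(ValueError):
        SystemState(float("inf"), 0, 0, 0, 0)


# ---------------------------------------------------------------------------
# visit probabilities
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "state, params, expected",
    [
        # only female insects present -> certain copulation attempt
        (SystemState(0, 0, 0, 0, 5), dict(a_M=0.7, a_F=0.3), (0.0, 0.0, 1.0)),
        # full symmetry of weights
        (SystemState(0, 1, 1, 0, 1), dict(a_M=1.0, a_F=1.0), (1 / 3, 1 / 3, 1 / 3)),
        # empty world: juveniles are not visit targets
        (SystemState(9, 0, 0, 3, 0), dict(a_M=1.0, a_F=1.0), (0.0, 0.0, 0.0)),
        # weighted case, checked by hand: D = 0.6 + 2.4 + 7.5
        (
            SystemState(0, 6, 1.5, 0, 7.5),
            dict(a_M=0.4, a_F=0.4),
            (2.4 / 10.5, 0.6 / 10.5, 7.5 / 10.5),
        ),
    ],
)
def test_visit_probabilities_examples(state, params, expected):
    probs = visit_probabilities(state, ModelParameters(**params))
    assert probs.as_tuple() == pytest.approx(expected, abs=1e-15)


def test_visit_probability_triple_rejects_broken_sum():
    with pytest.raises(ValueError):
        VisitProbabilities(0.5, 0.2, 0.2)
    with pytest.raises(ValueError):
        VisitProbabilities(1.2, -0.1, -0.1)


# ---------------------------------------------------------------------------
# lifetime visit statistics
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("impl", [visit_stats_combinatorial, visit_stats_closed_form])
class TestVisitStatistics:
    def test_no_female_plants_means_no_deaths(self, impl):
        """p_F = 0: nothing is ever counted for Q1 or P; Q2 is the binomial
        mean N * p_Y of copulations over a full life."""
        stats = impl(VisitProbabilities(0.7, 0.0, 0.3), 10)
        assert stats.Q1 == 0.0
        assert stats.P == 0.0
        assert stats.Q2 == pytest.approx(3.0, abs=1e-12)

    def test_single_visit_budget(self, impl):
        """N = 1: no visit can precede the single visit, so Q1 = 0 and Q2
        reduces to the chance p_Y that the one visit is a copulation."""
        probs = VisitProbabilities(0.2, 0.5, 0.3)
        stats = impl(probs, 1)
        assert stats.Q1 == 0.0
        assert stats.Q2 == pytest.approx(probs.p_Y, abs=1e-15)

    def test_certain_first_trap(self, impl):
        """p_F = 1: the first visit is always the fatal female-plant visit."""
        stats = impl(VisitProbabilities(0.0, 1.0, 0.0), 7)
        assert stats.P == pytest.approx(1.0, abs=1e-15)
        assert stats.Q1 == 0.0
        assert stats.Q2 == 0.0

    def test_trap_probability_geometric_form(self, impl):
        """P = 1 - (1-p_F)^N: survival of N independent visit events."""
        stats = impl(VisitProbabilities(0.45, 0.1, 0.45), 10)
        assert stats.P == pytest.approx(1.0 - 0.9**10, abs=1e-12)

    def test_two_visit_enumeration(self, impl):
        """N = 2, p_M = p_F = 0.5: enumerating all sequences by hand, the only
        pollen transfer is the sequence (male, female) with probability 1/4."""
        stats = impl(VisitProbabilities(0.5, 0.5, 0.0), 2)
        assert stats.Q1 == pytest.approx(0.25, abs=1e-15)
        assert stats.Q2 == 0.0
        assert stats.P == pytest.approx(0.75, abs=1e-15)

    def test_empty_world_gives_zero_stats(self, impl):
        stats = impl(VisitProbabilities(0.0, 0.0, 0.0), 10)
        assert (stats.Q1, stats.Q2, stats.P) == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("bad_n", [0, -3, 2.5, True])
    def test_rejects_invalid_visit_budget(self, impl, bad_n):
        with pytest.raises(ValueError):
            impl(VisitProbabilities(0.2, 0.5, 0.3), bad_n)


@st.composite
def probability_triples(draw):
    raw = draw(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=3, max_size=3).filter(
            lambda v: sum(v) > 1e-6
        )
    )
    total = sum(raw)
    return VisitProbabilities(raw[0] / total, raw[1] / total, raw[2] / total)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(probs=probability_triples(), n=st.integers(1, 20))
def test_closed_form_equals_combinatorial(probs, n):
    """The simplified geometric forms agree with the literal double sums to
    1e-12 absolute, and both respect the structural bounds."""
    a = visit_stats_combinatorial(probs, n)
    b = visit_stats_closed_form(probs, n)
    assert a.Q1 == pytest.approx(b.Q1, abs=1e-12)
    assert a.Q2 == pytest.approx(b.Q2, abs=1e-12)
    assert a.P == pytest.approx(b.P, abs=1e-12)
    assert -1e-12 <= b.Q1 <= n - 1 + 1e-12
    assert -1e-12 <= b.Q2 <= n + 1e-12
    assert -1e-12 <= b.P <= 1 + 1e-12


def _composition_probs(params, male_ratio, adult_total=None):
    total = params.K_X / 2 if adult_total is None else adult_total
    state = SystemState(0.0, total * male_ratio, total * (1 - male_ratio), 0.0, params.K_Y / 2)
    return visit_probabilities(state, params)


@pytest.mark.parametrize("adult_total", [15 / 4, 15 / 2, 15.0])
def test_attractiveness_monotonicity(defaults, adult_total):
    """With composition fixed (male ratio 0.8, Y_F = K_Y/2), raising the
    sex-generic attractiveness improves pollination (Q1, P up) and suppresses
    mating (Q2 down) -- robust to the assumed adult plant total."""
    a_grid = np.linspace(0.0, 2.0, 41)
    q1s, q2s, ps = [], [], []
    for a in a_grid:
        p = defaults.replace(a_M=float(a), a_F=float(a))
        stats = visit_stats_closed_form(_composition_probs(p, 0.8, adult_total), p.N)
        q1s.append(stats.Q1)
        q2s.append(stats.Q2)
        ps.append(stats.P)
    assert np.all(np.diff(q1s) >= -1e-12)
    assert np.all(np.diff(ps) >= -1e-12)
    assert np.all(np.diff(q2s) <= 1e-12)


def test_male_ratio_shape(defaults):
    """Over the plant male ratio at a = 0.4: Q1 rises then falls (one interior
    peak), Q2 is non-decreasing, P non-increasing."""
    grid = np.linspace(0.0, 1.0, 101)
    p04 = defaults.replace(a_M=0.4, a_F=0.4)
    stats = [visit_stats_closed_form(_composition_probs(p04, float(m)), p04.N) for m in grid]
    q1 = np.array([s.Q1 for s in stats])
    peak = int(np.argmax(q1))
    assert 0 < peak < len(grid) - 1
    assert np.all(np.diff(q1[: peak + 1]) >= -1e-12)
    assert np.all(np.diff(q1[peak:]) <= 1e-12)
    assert np.all(np.diff([s.Q2 for s in stats]) >= -1e-12)
    assert np.all(np.diff([s.P for s in stats]) <= 1e-12)


# ---------------------------------------------------------------------------
# interaction successes
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("success, half_sat", [(pollination_success, 1.0), (mating_success, 10.0)])
def test_saturating_success(success, half_sat):
    assert success(0.0, 5.0, half_sat) == 0.0
    assert success(half_sat, 1.0, half_sat) == 0.5  # pressure == half-saturation
    assert success(1e12, 1.0, half_sat) == pytest.approx(1.0, abs=1e-9)
    assert success(0.0, 0.0, 0.0) == 0.0  # defined as 0 even with A = 0


# ---------------------------------------------------------------------------
# full and plant-only derivatives
# ---------------------------------------------------------------------------


def test_zero_state_is_stationary(defaults):
    deriv = full_derivatives(SystemState(0, 0, 0, 0, 0), defaults)
    assert deriv.as_tuple() == (0.0, 0.0, 0.0, 0.0, 0.0)
    assert plant_only_derivatives(0, 0, 0, defaults) == (0.0, 0.0, 0.0)


def test_full_reduces_to_plant_only_without_insects(defaults):
    state = SystemState(1.3, 2.7, 0.9, 0.0, 0.0)
    full = full_derivatives(state, defaults)
    sub = plant_only_derivatives(1.3, 2.7, 0.9, defaults)
    assert full.as_tuple()[:3] == pytest.approx(sub, abs=1e-15)
    assert full.dY_M == full.dY_F == 0.0


def test_no_recruitment_means_decreasing_plant_total(defaults):
    p = defaults.replace(r_VM=0.0, r_VF=0.0)
    d = plant_only_derivatives(0.5, 1.0, 0.25, p)
    assert sum(d) < 0.0


def test_full_derivatives_regression_fixture(defaults):
    """Five derivatives at (1, 2, 1, 3, 4), frozen from an exact rational
    evaluation of the printed right-hand sides (symbolic arithmetic)."""
    deriv = full_derivatives(SystemState(1, 2, 1, 3, 4), defaults)
    expected = (
        0.3562584386922067,
        0.015144433254893728,
        0.004855566745106272,
        0.2027931829391239,
        0.929087522226329,
    )
    assert deriv.as_tuple() == pytest.approx(expected, abs=1e-14)


# ---------------------------------------------------------------------------
# persistence condition
# ---------------------------------------------------------------------------


def test_persistence_index_zero_without_vegetative_reproduction(defaults):
    assert persistence_index(defaults.replace(r_VM=0.0, r_VF=0.0)) == 0.0


def test_persistence_index_boundary_value(defaults):
    """Direct arithmetic: (0.05/0.065) * (0.013/0.02 + 0.5*1.3) = 1."""
    p = defaults.replace(g_MF=0.01, r_VM=0.013, r_VF=0.013)
    assert persistence_index(p) == pytest.approx(1.0, abs=1e-12)


def test_persistence_index_monotone_in_reproduction_and_maturation(defaults):
    base = persistence_index(defaults)
    assert persistence_index(defaults.replace(r_VM=defaults.r_VM * 2)) > base
    assert persistence_index(defaults.replace(r_VF=defaults.r_VF * 2)) > base
    assert persistence_index(defaults.replace(g_JM=defaults.g_JM * 2)) > base


def test_persistence_index_names_offending_denominator():
    p = ModelParameters(d_F=0.0, g_MF=0.02)
    with pytest.raises(ValueError, match="d_F"):
        persistence_index(p)


def test_persistence_boundary_reference_value(defaults):
    assert persistence_boundary_r(defaults.replace(g_MF=0.01)) == pytest.approx(
        0.013, abs=1e-12
    )


def test_boundary_is_fixed_point_of_index(defaults):
    for g_mf in (0.005, 0.01, 0.03):
        p = defaults.replace(g_MF=g_mf)
        r_star = persistence_boundary_r(p)
        assert persistence_index(p.replace(r_VM=r_star, r_VF=r_star)) == pytest.approx(
            1.0, abs=1e-12
        )


def test_boundary_decreases_with_maturation_rate(defaults):
    slow = persistence_boundary_r(defaults.replace(g_JM=0.02))
    fast = persistence_boundary_r(defaults.replace(g_JM=0.1))
    assert fast < slow
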