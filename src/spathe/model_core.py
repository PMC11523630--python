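"""Core model of a lethal deceptive pollination system.

A sequentially hermaphroditic trap-flowered plant (juvenile -> adult male ->
adult female, with reversal) deceives male fungus gnats into visiting its
flowers by mimicking the sex pheromone of female gnats.  Male flowers let the
visitor escape with pollen; female flowers imprison him until death, which is
the only route to pollination.  This module holds every symbol of the model and
implements its equations as pure, deterministic functions:

* per-visit choice probabilities of a male insect (``visit_probabilities``),
* his expected lifetime visit statistics Q1, Q2, P, both as the literal
  combinatorial double sums (``visit_stats_combinatorial``) and as the
  algebraically simplified geometric forms (``visit_stats_closed_form``),
* Holling type-II pollination and mating success,
* the five coupled plant-insect derivatives (``full_derivatives``) and the
  insect-free plant subsystem (``plant_only_derivatives``),
* the analytic plant persistence condition (``persistence_index``,
  ``persistence_boundary_r``).

All abundances are at the flower scale (one plant == one inflorescence) and
model time is dimensionless.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

__all__ = [
    "ModelParameters",
    "SystemState",
    "VisitProbabilities",
    "VisitStatistics",
    "StateDerivative",
    "visit_probabilities",
    "visit_stats_combinatorial",
    "visit_stats_closed_form",
    "pollination_success",
    "mating_success",
    "full_derivatives",
    "plant_only_derivatives",
    "persistence_index",
    "persistence_boundary_r",
]

#: Probability-conservation tolerance for a VisitProbabilities triple.
PROB_TOL = 1e-12


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter vector of the model.

    Defaults are the calibrated reference set: the fixed life-history values
    plus, for the quantities the analyses sweep (attractiveness ``a_M``/``a_F``,
    vegetative rates ``r_VM``/``r_VF``, sex-change rate ``g_MF``), the
    calibrated coexistence values a = 0.4, r_V = 0.02, g_MF = 0.01.

    Attributes
    ----------
    a_M, a_F
        Attractiveness of male / female plants to male insects, relative to a
        female insect (dimensionless weight >= 0; 1 means indistinguishable).
    r_VM, r_VF
        Vegetative (cormlet) reproduction rates of male / female plants,
        per unit time.
    r_P
        Sexual reproduction rate via pollination, per unit time.
    K_X, K_Y
        Recruitment capacities of plant and insect (logistic ceiling on
        juvenile / offspring recruitment), abundance units.
    g_JM, g_MF, g_FM
        Stage-transition rates: juvenile -> male (net maturation),
        male -> female (sex change), female -> male (sex reversal).
    d_J, d_M, d_F
        Plant death rates by stage.
    s
        Male birth ratio of the insect, in [0, 1].
    f
        Female-offspring production coefficient of the insect.
    d_Y
        Insect natural death rate.
    A_X, A_Y
        Half-saturation coefficients of pollination and mating success.
    q
        Scaling of the lifetime trap probability P to a per-unit-time death
        rate of male insects.
    N
        Maximum lifetime number of visits by a male insect (integer >= 1).
    """

    a_M: float = 0.4
    a_F: float = 0.4
    r_VM: float = 0.02
    r_VF: float = 0.02
    r_P: float = 1.0
    K_X: float = 15.0
    K_Y: float = 15.0
    g_JM: float = 0.05
    g_MF: float = 0.01
    g_FM: float = 0.01
    d_J: float = 0.015
    d_M: float = 0.01
    d_F: float = 0.01
    s: float = 0.5
    f: float = 2.0
    d_Y: float = 0.1
    A_X: float = 1.0
    A_Y: float = 10.0
    q: float = 0.5
    N: int = 10

    def __post_init__(self) -> None:
        # single validation pass; every downstream operation assumes it ran
        for name in (
            "a_M", "a_F", "r_VM", "r_VF", "r_P", "g_JM", "g_MF", "g_FM",
            "d_J", "d_M", "d_F", "f", "d_Y", "A_X", "A_Y", "q",
        ):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {value!r}")
        for name in ("K_X", "K_Y"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"capacity {name} must be finite and > 0, got {value!r}")
        if not (0.0 <= self.s <= 1.0):
            raise ValueError(f"male birth ratio s must lie in [0, 1], got {self.s!r}")
        if not isinstance(self.N, int) or isinstance(self.N, bool) or self.N < 1:
            raise ValueError(f"visit budget N must be an integer >= 1, got {self.N!r}")

    def replace(self, **overrides: float) -> "ModelParameters":
        """Return a copy with ``overrides`` applied (re-validated)."""
        return dataclasses.replace(self, **overrides)

    # -- flat-key serialization -------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        if "N" in data:
            n = data["N"]
            # JSON has no integer/float distinction; accept exact integers
            if isinstance(n, float) and n.is_integer():
                data = {**data, "N": int(n)}
        return cls(**data)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelParameters":
        path = Path(source) if not str(source).lstrip().startswith("{") else None
        text = path.read_text() if path is not None else str(source)
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class SystemState:
    """The five abundances at one time point: plants (juvenile, adult male,
    adult female) and insects (male, female)."""

    X_J: float
    X_M: float
    X_F: float
    Y_M: float
    Y_F: float

    def __post_init__(self) -> None:
        for name, value in self.items():
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"abundance {name} must be finite and >= 0, got {value!r}")

    def items(self) -> Iterator[tuple[str, float]]:
        return iter(dataclasses.asdict(self).items())

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.X_J, self.X_M, self.X_F, self.Y_M, self.Y_F)

    @property
    def plant_total(self) -> float:
        return self.X_J + self.X_M + self.X_F

    @property
    def insect_total(self) -> float:
        return self.Y_M + self.Y_F


@dataclass(frozen=True)
class VisitProbabilities:
    """Per-visit-event probabilities that a male insect lands on a male plant
    (p_M), a female plant (p_F, fatal) or a female insect (p_Y).

    Either the three sum to 1, or all three are exactly 0 (the empty-world
    convention when no visit target exists).
    """

    p_M: float
    p_F: float
    p_Y: float

    def __post_init__(self) -> None:
        for name, value in (("p_M", self.p_M), ("p_F", self.p_F), ("p_Y", self.p_Y)):
            if not (0.0 <= value <= 1.0) or not math.isfinite(value):
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        total = self.p_M + self.p_F + self.p_Y
        if total != 0.0 and abs(total - 1.0) > PROB_TOL:
            raise ValueError(
                f"visit probabilities must sum to 1 (or all be 0), got sum {total!r}"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_M, self.p_F, self.p_Y)

    @property
    def is_empty_world(self) -> bool:
        return self.p_M == self.p_F == self.p_Y == 0.0


@dataclass(frozen=True)
class VisitStatistics:
    """Lifetime visit expectations of a male insect with visit budget N.

    Q1 : expected number of male-plant visits before death at a female plant
         (0 <= Q1 <= N-1); the pollen-transfer statistic.
    Q2 : expected number of female-insect visits, i.e. copulations
         (0 <= Q2 <= N).
    P  : probability of ever visiting (and dying at) a female plant
         during the lifetime (0 <= P <= 1).
    """

    Q1: float
    Q2: float
    P: float


@dataclass(frozen=True)
class StateDerivative:
    """Time derivatives of the five SystemState components."""

    dX_J: float
    dX_M: float
    dX_F: float
    dY_M: float
    dY_F: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.dX_J, self.dX_M, self.dX_F, self.dY_M, self.dY_F)


# ---------------------------------------------------------------------------
# Visit choice and lifetime visit statistics
# ---------------------------------------------------------------------------


def visit_probabilities(state: SystemState, params: ModelParameters) -> VisitProbabilities:
    """Per-visit choice probabilities of a male insect.

    Targets are weighted by attractiveness: a_M per male plant, a_F per female
    plant, 1 per female insect.  Juvenile plants do not flower and are never
    visited.  With no targets at all, returns (0, 0, 0).
    """
    weight_m = params.a_M * state.X_M
    weight_f = params.a_F * state.X_F
    denom = weight_m + weight_f + state.Y_F
    if denom == 0.0:
        return VisitProbabilities(0.0, 0.0, 0.0)
    return VisitProbabilities(weight_m / denom, weight_f / denom, state.Y_F / denom)


def _check_n(N: int) -> None:
    if not isinstance(N, int) or isinstance(N, bool) or N < 1:
        raise ValueError(f"visit budget N must be an integer >= 1, got {N!r}")


def visit_stats_combinatorial(probs: VisitProbabilities, N: int) -> VisitStatistics:
    """Q1, Q2, P by literal evaluation of the combinatorial double sums.

    Each inner sum enumerates the k-combinations of male-plant (or
    female-insect) visits among j prior visit events; binomial coefficients are
    computed in exact integer arithmetic before any floating multiplication.
    Serves as the slow, transparent reference for
    :func:`visit_stats_closed_form`.
    """
    _check_n(N)
    p_M, p_F, p_Y = probs.as_tuple()
    if probs.is_empty_world:
        return VisitStatistics(0.0, 0.0, 0.0)

    q1 = 0.0
    q2_before_death = 0.0
    for j in range(N):  # j prior visits survived, death on visit j+1
        for k in range(j + 1):
            comb = math.comb(j, k)
            q1 += k * comb * p_M**k * p_Y ** (j - k)
            q2_before_death += k * comb * p_Y**k * p_M ** (j - k)
    q1 *= p_F
    q2_before_death *= p_F

    # copulations over a full N-visit life that never touches a female plant
    q2_survivor = sum(
        k * math.comb(N, k) * p_Y**k * p_M ** (N - k) for k in range(N + 1)
    )

    p_death = sum(p_F * (1.0 - p_F) ** k for k in range(N))
    return VisitStatistics(q1, q2_before_death + q2_survivor, p_death)


def visit_stats_closed_form(
    probs: VisitProbabilities, N: int, lethal: bool = True
) -> VisitStatistics:
    """Q1, Q2, P via the algebraically simplified (geometric) forms.

    Identical to :func:`visit_stats_combinatorial` to ~1e-12 absolute; this is
    the fast path used inside the dynamics.  With ``lethal=False`` the
    female-plant visit does not kill: Q1 counts male-plant visits made while
    still carrying pollen (before the first female-plant visit), Q2 counts
    copulations over the full N-visit life, and P retains its meaning as the
    probability of at least one female-plant visit.
    """
    _check_n(N)
    p_M, p_F, p_Y = probs.as_tuple()
    if probs.is_empty_world:
        return VisitStatistics(0.0, 0.0, 0.0)

    surv = 1.0 - p_F
    # S = sum_{j=1..N-1} j * (1-p_F)^(j-1)
    s_sum = sum(j * surv ** (j - 1) for j in range(1, N))
    p_death = 1.0 - surv**N
    if lethal:
        q1 = p_F * p_M * s_sum
        q2 = p_F * p_Y * s_sum + N * p_Y * surv ** (N - 1)
    else:
        q1 = p_M * (p_F * s_sum + N * surv ** (N - 1))
        q2 = N * p_Y
    return VisitStatistics(q1, q2, p_death)


# ---------------------------------------------------------------------------
# Holling type-II interaction successes
# ---------------------------------------------------------------------------


def pollination_success(Y_M: float, Q1: float, A_X: float) -> float:
    """Fraction of female plants pollinated: Y_M*Q1 / (A_X + Y_M*Q1).

    Saturating (Holling type II) in the pollen-delivery pressure Y_M*Q1, with
    half-saturation at A_X.  Defined as 0 when the pressure is 0, even if
    A_X = 0.
    """
    pressure = Y_M * Q1
    if pressure == 0.0:
        return 0.0
    return pressure / (A_X + pressure)


def mating_success(Y_M: float, Q2: float, A_Y: float) -> float:
    """Fraction of female insects mated: Y_M*Q2 / (A_Y + Y_M*Q2)."""
    pressure = Y_M * Q2
    if pressure == 0.0:
        return 0.0
    return pressure / (A_Y + pressure)


# ---------------------------------------------------------------------------
# Coupled dynamics
# ---------------------------------------------------------------------------


def _derivatives_raw(
    x_j: float, x_m: float, x_f: float, y_m: float, y_f: float, p: ModelParameters
) -> tuple[float, float, float, float, float]:
    """The five derivatives from raw non-negative floats (fast path used by
    the integrator; no dataclass construction)."""
    weight_m = p.a_M * x_m
    weight_f = p.a_F * x_f
    denom = weight_m + weight_f + y_f
    if denom == 0.0:
        q1 = q2 = p_death = 0.0
    else:
        p_m = weight_m / denom
        p_f = weight_f / denom
        p_y = y_f / denom
        surv = 1.0 - p_f
        s_sum = sum(j * surv ** (j - 1) for j in range(1, p.N))
        q1 = p_f * p_m * s_sum
        q2 = p_f * p_y * s_sum + p.N * p_y * surv ** (p.N - 1)
        p_death = 1.0 - surv**p.N

    phi_x = pollination_success(y_m, q1, p.A_X)
    phi_y = mating_success(y_m, q2, p.A_Y)

    plant_room = 1.0 - (x_j + x_m + x_f) / p.K_X
    insect_room = 1.0 - (y_m + y_f) / p.K_Y
    reversal = p.g_FM * phi_x * x_f  # pollination-driven female -> male flux

    d_xj = (
        (p.r_VM * x_m + (p.r_VF + p.r_P * phi_x) * x_f) * plant_room
        - p.g_JM * x_j
        - p.d_J * x_j
    )
    d_xm = p.g_JM * x_j - p.g_MF * x_m + reversal - p.d_M * x_m
    d_xf = p.g_MF * x_m - reversal - p.d_F * x_f
    recruit = p.f * phi_y * insect_room * y_f
    d_ym = p.s * recruit - (p.d_Y + p.q * p_death) * y_m
    d_yf = (1.0 - p.s) * recruit - p.d_Y * y_f
    return (d_xj, d_xm, d_xf, d_ym, d_yf)


def full_derivatives(state: SystemState, params: ModelParameters) -> StateDerivative:
    """Right-hand side of the full coupled plant-insect system.

    Composes visit probabilities -> closed-form visit statistics -> Holling
    successes, then assembles:

    * juvenile production (vegetative from both adult sexes, sexual from
      pollinated females) throttled by the logistic recruitment room
      (1 - (X_J+X_M+X_F)/K_X), minus maturation and death;
    * adult fluxes: maturation in, sex change male->female at g_MF, sex
      reversal female->male at g_FM times pollination success, stage deaths;
    * insect recruitment s·f·Phi_Y·(1 - (Y_M+Y_F)/K_Y)·Y_F into males and
      (1-s)·(...) into females; male insects additionally die at rate q·P
      from being trapped in female flowers.
    """
    return StateDerivative(*_derivatives_raw(*state.as_tuple(), params))


def plant_only_derivatives(
    X_J: float, X_M: float, X_F: float, params: ModelParameters
) -> tuple[float, float, float]:
    """Plant subsystem in the absence of insects: no pollination term and no
    pollination-driven sex reversal, otherwise the same stage structure."""
    plant_room = 1.0 - (X_J + X_M + X_F) / params.K_X
    d_xj = (
        (params.r_VM * X_M + params.r_VF * X_F) * plant_room
        - params.g_JM * X_J
        - params.d_J * X_J
    )
    d_xm = params.g_JM * X_J - params.g_MF * X_M - params.d_M * X_M
    d_xf = params.g_MF * X_M - params.d_F * X_F
    return (d_xj, d_xm, d_xf)


# ---------------------------------------------------------------------------
# Plant persistence without pollinators
# ---------------------------------------------------------------------------


def persistence_index(params: ModelParameters) -> float:
    """Lifetime fitness of a rare plant lineage without pollinators.

    The product of the probability a juvenile survives to the adult male stage,
    g_JM/(g_JM+d_J), and the expected number of juveniles produced per adult:
    r_VM/(g_MF+d_M) as a male plus the chance g_MF/(g_MF+d_M) of surviving to
    the female stage times r_VF/d_F.  The plant persists alone iff the index
    exceeds 1.
    """
    for name, value in (
        ("g_JM + d_J", params.g_JM + params.d_J),
        ("g_MF + d_M", params.g_MF + params.d_M),
        ("d_F", params.d_F),
    ):
        if value <= 0.0:
            raise ValueError(f"persistence index undefined: {name} must be > 0")
    maturation_prob = params.g_JM / (params.g_JM + params.d_J)
    male_output = params.r_VM / (params.g_MF + params.d_M)
    female_output = (params.g_MF / (params.g_MF + params.d_M)) * (params.r_VF / params.d_F)
    return maturation_prob * (male_output + female_output)


def persistence_boundary_r(params: ModelParameters) -> float:
    """Common vegetative rate r (r_VM = r_VF = r) at which the persistence
    index equals 1, in closed form.  Below r* the plant cannot persist alone."""
    for name, value in (
        ("g_JM", params.g_JM),
        ("g_MF + d_M", params.g_MF + params.d_M),
        ("d_F", params.d_F),
        ("g_JM + d_J", params.g_JM + params.d_J),
    ):
        if value <= 0.0:
            raise ValueError(f"persistence boundary undefined: {name} must be > 0")
    inv_maturation = (params.g_JM + params.d_J) / params.g_JM
    per_r_output = 1.0 / (params.g_MF + params.d_M) + params.g_MF / (
        (params.g_MF + params.d_M) * params.d_F
    )
    return inv_maturation / per_r_output
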