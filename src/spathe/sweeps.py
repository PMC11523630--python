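"""Parameter-space analyses: regime maps, response curves, sensitivity scans.

Reproduces the model's survey analyses over disturbance-relevant parameters:

* :func:`regime_map` — a 2-D grid of steady-state outcomes over two swept
  parameters (e.g. sex-change rate vs vegetative reproduction, or the two
  recruitment capacities), with the analytic plant-persistence boundary
  attached where it applies;
* :func:`attractiveness_response` — steady-state abundances and sex ratios
  along a sex-generic floral-attractiveness gradient, under either of the two
  empirically motivated life-history scenarios;
* :func:`behaviour_response` — the static visit statistics (Q1, Q2, P) of a
  male insect as a function of attractiveness or plant sex ratio;
* :func:`sensitivity_scan` — one-at-a-time parameter variation around a base
  set, reporting the steady-state summary and outcome per value.

Two scenario presets bracket the empirical life histories: the "first"
scenario has no vegetative reproduction and a low sex-change rate
(r_V = 0, g_MF = 0.005, species fully dependent on pollination); the "second"
has both high (r_V = 0.02, g_MF = 0.01, a strong cormlet producer).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    EXTINCTION_THRESHOLD,
    T_END,
    WINDOW_FRACTION,
    Outcome,
    SolverSettings,
    SteadyStateSummary,
    run_to_outcome,
)
from .model_core import (
    ModelParameters,
    SystemState,
    VisitProbabilities,
    persistence_boundary_r,
    visit_probabilities,
    visit_stats_closed_form,
)

__all__ = [
    "AxisSpec",
    "RegimeMap",
    "ScenarioPreset",
    "BehaviourResponse",
    "SCENARIO_PRESETS",
    "resolve_parameter",
    "regime_map",
    "attractiveness_response",
    "behaviour_response",
    "sensitivity_scan",
    "write_regime_map",
]

#: Sweep-axis aliases that set a linked parameter pair at once.
LINKED_PARAMETERS: dict[str, tuple[str, ...]] = {
    "r_V": ("r_VM", "r_VF"),
    "a": ("a_M", "a_F"),
}

_FIELD_NAMES = set(ModelParameters().to_dict())


def resolve_parameter(name: str) -> tuple[str, ...]:
    """Map a sweep-axis name to the ModelParameters fields it sets."""
    if name in LINKED_PARAMETERS:
        return LINKED_PARAMETERS[name]
    if name in _FIELD_NAMES:
        return (name,)
    raise ValueError(
        f"unknown parameter {name!r}; expected a model symbol or one of "
        f"{sorted(LINKED_PARAMETERS)}"
    )


@dataclass(frozen=True)
class AxisSpec:
    """One sweep axis: a parameter name (or linked pair alias), a linear range
    and a point count."""

    name: str
    min: float
    max: float
    n_points: int
    spacing: str = "linear"

    def __post_init__(self) -> None:
        resolve_parameter(self.name)
        if not self.min < self.max:
            raise ValueError(f"axis {self.name}: min must be < max")
        if self.n_points < 2:
            raise ValueError(f"axis {self.name}: n_points must be >= 2")
        if self.spacing != "linear":
            raise ValueError(f"axis {self.name}: only linear spacing is supported")

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.min, self.max, self.n_points)

    @property
    def fields(self) -> tuple[str, ...]:
        return resolve_parameter(self.name)


@dataclass(frozen=True)
class ScenarioPreset:
    """Named life-history scenario: overrides for the vegetative rates and the
    male-to-female transition rate."""

    name: str
    r_VM: float
    r_VF: float
    g_MF: float

    def apply(self, base: ModelParameters) -> ModelParameters:
        return base.replace(r_VM=self.r_VM, r_VF=self.r_VF, g_MF=self.g_MF)


SCENARIO_PRESETS: dict[str, ScenarioPreset] = {
    "first": ScenarioPreset("first", r_VM=0.0, r_VF=0.0, g_MF=0.005),
    "second": ScenarioPreset("second", r_VM=0.02, r_VF=0.02, g_MF=0.01),
}


@dataclass(frozen=True)
class RegimeMap:
    """Classified steady states over a 2-D parameter grid.

    ``outcomes[i][j]`` and ``summaries[i][j]`` correspond to
    ``axis1.values[i]`` x ``axis2.values[j]``.  When one axis is the linked
    vegetative rate and the other the sex-change rate, ``boundary`` holds the
    analytic plant-persistence frontier as (g_MF value, r*) pairs.
    """

    axis1: AxisSpec
    axis2: AxisSpec
    outcomes: list[list[Outcome]]
    summaries: list[list[SteadyStateSummary]]
    boundary: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.outcomes) != self.axis1.n_points or any(
            len(row) != self.axis2.n_points for row in self.outcomes
        ):
            raise ValueError("outcome grid does not match axis specs")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per grid cell."""
        rows = []
        for i, v1 in enumerate(self.axis1.values):
            for j, v2 in enumerate(self.axis2.values):
                s = self.summaries[i][j]
                rows.append(
                    {
                        f"{self.axis1.name}": v1,
                        f"{self.axis2.name}": v2,
                        "outcome": self.outcomes[i][j].value,
                        "mean_X_J": s.mean_X_J,
                        "mean_X_M": s.mean_X_M,
                        "mean_X_F": s.mean_X_F,
                        "mean_Y_M": s.mean_Y_M,
                        "mean_Y_F": s.mean_Y_F,
                        "plant_male_ratio": s.plant_male_ratio,
                        "insect_male_ratio": s.insect_male_ratio,
                    }
                )
        return pd.DataFrame(rows)


def _apply_axis_value(params: ModelParameters, axis: AxisSpec, value: float) -> ModelParameters:
    return params.replace(**{f: float(value) for f in axis.fields})


def regime_map(
    base: ModelParameters,
    axis1: AxisSpec,
    axis2: AxisSpec,
    init: SystemState | None = None,
    t_end: float = T_END,
    window_fraction: float = WINDOW_FRACTION,
    threshold: float = EXTINCTION_THRESHOLD,
    settings: SolverSettings | None = None,
) -> RegimeMap:
    """Classify the steady state at every cell of a 2-D parameter grid.

    Each cell applies both axis overrides to ``base`` and runs the standard
    protocol from the default initial state (or ``init`` if given).
    """
    if set(axis1.fields) & set(axis2.fields):
        raise ValueError("sweep axes must name distinct parameters")
    outcomes: list[list[Outcome]] = []
    summaries: list[list[SteadyStateSummary]] = []
    for v1 in axis1.values:
        row_o: list[Outcome] = []
        row_s: list[SteadyStateSummary] = []
        p1 = _apply_axis_value(base, axis1, v1)
        for v2 in axis2.values:
            p = _apply_axis_value(p1, axis2, v2)
            summary, outcome = run_to_outcome(
                p,
                init=init,
                t_end=t_end,
                window_fraction=window_fraction,
                threshold=threshold,
                settings=settings,
            )
            row_o.append(outcome)
            row_s.append(summary)
        outcomes.append(row_o)
        summaries.append(row_s)

    boundary = _persistence_boundary_curve(base, axis1, axis2)
    return RegimeMap(axis1, axis2, outcomes, summaries, boundary)


def _persistence_boundary_curve(
    base: ModelParameters, axis1: AxisSpec, axis2: AxisSpec
) -> np.ndarray | None:
    """(g_MF, r*) frontier when one axis sweeps g_MF and the other r_V."""
    axes = {axis1.name: axis1, axis2.name: axis2}
    if "g_MF" not in axes or "r_V" not in axes:
        return None
    g_axis = axes["g_MF"]
    pts = []
    for g in g_axis.values:
        pts.append((float(g), persistence_boundary_r(base.replace(g_MF=float(g)))))
    return np.asarray(pts)


def attractiveness_response(
    base: ModelParameters,
    preset: ScenarioPreset | str,
    a_grid: Sequence[float],
    t_end: float = T_END,
    window_fraction: float = WINDOW_FRACTION,
    threshold: float = EXTINCTION_THRESHOLD,
    settings: SolverSettings | None = None,
) -> pd.DataFrame:
    """Steady-state response to sex-generic floral attractiveness.

    For each a in ``a_grid`` (setting a_M = a_F = a under the scenario
    preset) reports plant and insect totals relative to their capacities and
    the two male ratios, plus the outcome.
    """
    if isinstance(preset, str):
        preset = SCENARIO_PRESETS[preset]
    params0 = preset.apply(base)
    rows = []
    for a in a_grid:
        if a < 0:
            raise ValueError(f"attractiveness must be >= 0, got {a!r}")
        p = params0.replace(a_M=float(a), a_F=float(a))
        summary, outcome = run_to_outcome(
            p,
            t_end=t_end,
            window_fraction=window_fraction,
            threshold=threshold,
            settings=settings,
        )
        rows.append(
            {
                "a": float(a),
                "plant_total_rel": summary.plant_total / p.K_X,
                "insect_total_rel": summary.insect_total / p.K_Y,
                "plant_male_ratio": summary.plant_male_ratio,
                "insect_male_ratio": summary.insect_male_ratio,
                "outcome": outcome.value,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BehaviourResponse:
    """Visit-statistic curves plus, per visit budget N, the smallest grid
    value maximizing Q1."""

    mode: str
    table: pd.DataFrame
    q1_argmax: dict[int, float]


def behaviour_response(
    params: ModelParameters,
    mode: str,
    grid: Sequence[float],
    N_list: Sequence[int] = (5, 10, 20),
    plant_male_ratio: float = 0.8,
    fixed_a: float = 0.4,
) -> BehaviourResponse:
    """Static visit statistics over attractiveness or plant sex ratio.

    The insect composition is fixed at Y_F = K_Y/2 and the adult plant total
    at K_X/2 (juveniles are never visited and are excluded).  In
    ``"attractiveness"`` mode the plant male ratio is held at
    ``plant_male_ratio`` while a_M = a_F sweeps ``grid``; in ``"male_ratio"``
    mode attractiveness is held at ``fixed_a`` while the male share of the
    adult plant total sweeps ``grid``.
    """
    if mode not in ("attractiveness", "male_ratio"):
        raise ValueError(f"mode must be 'attractiveness' or 'male_ratio', got {mode!r}")
    y_f = params.K_Y / 2.0
    plant_total = params.K_X / 2.0
    rows = []
    for value in grid:
        if mode == "attractiveness":
            if value < 0:
                raise ValueError(f"attractiveness must be >= 0, got {value!r}")
            a = float(value)
            m = plant_male_ratio
        else:
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"male ratio must lie in [0, 1], got {value!r}")
            a = fixed_a
            m = float(value)
        p = params.replace(a_M=a, a_F=a)
        state = SystemState(0.0, plant_total * m, plant_total * (1.0 - m), 0.0, y_f)
        probs = visit_probabilities(state, p)
        for n in N_list:
            stats = visit_stats_closed_form(probs, n)
            rows.append(
                {mode: float(value), "N": int(n), "Q1": stats.Q1, "Q2": stats.Q2, "P": stats.P}
            )
    table = pd.DataFrame(rows)
    argmax: dict[int, float] = {}
    for n in N_list:
        sub = table[table["N"] == n].reset_index(drop=True)
        # first occurrence of the maximum == smallest maximizing grid value
        argmax[int(n)] = float(sub[mode].iloc[int(np.argmax(sub["Q1"].to_numpy()))])
    return BehaviourResponse(mode, table, argmax)


def sensitivity_scan(
    base: ModelParameters,
    parameter: str,
    values: Sequence[float],
    preset: ScenarioPreset | str | None = None,
    t_end: float = T_END,
    window_fraction: float = WINDOW_FRACTION,
    threshold: float = EXTINCTION_THRESHOLD,
    settings: SolverSettings | None = None,
) -> pd.DataFrame:
    """One-at-a-time sensitivity: vary ``parameter`` over ``values`` with all
    other parameters at their base (optionally preset-adjusted) values."""
    fields = resolve_parameter(parameter)
    if preset is not None:
        if isinstance(preset, str):
            preset = SCENARIO_PRESETS[preset]
        base = preset.apply(base)
    rows = []
    for value in values:
        p = base.replace(**{f: float(value) for f in fields})
        summary, outcome = run_to_outcome(
            p,
            t_end=t_end,
            window_fraction=window_fraction,
            threshold=threshold,
            settings=settings,
        )
        row = {parameter: float(value), "outcome": outcome.value}
        row.update(summary.to_dict())
        row.pop("window")
        rows.append(row)
    return pd.DataFrame(rows)


def write_regime_map(
    rmap: RegimeMap,
    base: ModelParameters,
    csv_path: str | Path,
    meta_path: str | Path | None = None,
) -> None:
    """Long-format CSV of the grid plus a JSON sidecar echoing axes, boundary
    and the full base parameter set."""
    rmap.to_frame().to_csv(csv_path, index=False)
    if meta_path is not None:
        meta = {
            "axis1": {"name": rmap.axis1.name, "min": rmap.axis1.min,
                      "max": rmap.axis1.max, "n_points": rmap.axis1.n_points},
            "axis2": {"name": rmap.axis2.name, "min": rmap.axis2.min,
                      "max": rmap.axis2.max, "n_points": rmap.axis2.n_points},
            "parameters": base.to_dict(),
            "boundary": None if rmap.boundary is None else rmap.boundary.tolist(),
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
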