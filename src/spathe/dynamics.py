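"""Integration, steady-state summarization and outcome classification.

Simulation protocol: start from juveniles colonizing an insect steady state
(X_J = 1, adults 0, each insect sex at K_Y/2), integrate the coupled system to
t = 50 000, average abundances over the last 10 % of the run, and call a
population extinct when its window-mean total falls below 0.001.  During
integration the same 0.001 threshold is applied as an event-based extinction
clamp: when a population's running total crosses it from above, its components
are set to zero and integration continues, preventing biologically meaningless
rebounds from infinitesimal abundances.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import ModelParameters, SystemState, _derivatives_raw

__all__ = [
    "SolverSettings",
    "Trajectory",
    "SteadyStateSummary",
    "Outcome",
    "IntegrationError",
    "default_initial_state",
    "integrate",
    "summarize",
    "classify",
    "run_to_outcome",
    "bistability_probe",
    "is_bistable",
    "write_trajectory_csv",
    "write_summary_json",
]

#: Protocol constants: integration horizon, averaging window, extinction cut.
T_END = 50_000.0
WINDOW_FRACTION = 0.1
EXTINCTION_THRESHOLD = 1e-3

#: Below this, a window-mean sex pair is considered absent and its ratio
#: undefined (reported as None rather than 0/0).
RATIO_EPS = 1e-12


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the failing time."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (t = {t_fail:g})")
        self.t_fail = t_fail


@dataclass(frozen=True)
class SolverSettings:
    """Adaptive-integrator settings.

    LSODA switches automatically between non-stiff and stiff machinery, which
    suits both the transient and the near-equilibrium tail of these runs.
    ``n_samples`` controls the uniform output grid the trajectory is sampled
    on (the solver's internal steps remain adaptive).
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"
    extinction_threshold: float = EXTINCTION_THRESHOLD
    n_samples: int = 2001

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.extinction_threshold <= 0:
            raise ValueError("extinction threshold must be > 0")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


@dataclass(frozen=True)
class Trajectory:
    """A sampled solution: times (strictly increasing), states (n x 5 array
    in X_J, X_M, X_F, Y_M, Y_F order), the parameters used, and the list of
    extinction-clamp events as (time, population, "zeroed") records."""

    times: np.ndarray
    states: np.ndarray
    params: ModelParameters
    events: list[tuple[float, str, str]] = field(default_factory=list)

    def state_at(self, index: int) -> SystemState:
        return SystemState(*(float(v) for v in self.states[index]))


@dataclass(frozen=True)
class SteadyStateSummary:
    """Time-weighted mean abundances over the evaluation window, plus sex
    ratios formed from those means (None when both sexes are absent)."""

    mean_X_J: float
    mean_X_M: float
    mean_X_F: float
    mean_Y_M: float
    mean_Y_F: float
    plant_male_ratio: float | None
    insect_male_ratio: float | None
    window: tuple[float, float]

    @property
    def plant_total(self) -> float:
        return self.mean_X_J + self.mean_X_M + self.mean_X_F

    @property
    def insect_total(self) -> float:
        return self.mean_Y_M + self.mean_Y_F

    def to_dict(self) -> dict:
        return {
            "mean_X_J": self.mean_X_J,
            "mean_X_M": self.mean_X_M,
            "mean_X_F": self.mean_X_F,
            "mean_Y_M": self.mean_Y_M,
            "mean_Y_F": self.mean_Y_F,
            "plant_male_ratio": self.plant_male_ratio,
            "insect_male_ratio": self.insect_male_ratio,
            "window": list(self.window),
        }


class Outcome(enum.Enum):
    """Four-way steady-state classification at the extinction threshold."""

    COEXIST = "coexist"
    PLANT_ONLY = "plant_only"
    INSECT_ONLY = "insect_only"
    CO_EXTINCT = "co_extinct"


def default_initial_state(params: ModelParameters) -> SystemState:
    """Juveniles colonizing a plant-free insect steady state:
    (X_J, X_M, X_F, Y_M, Y_F) = (1, 0, 0, K_Y/2, K_Y/2)."""
    half = params.K_Y / 2.0
    return SystemState(1.0, 0.0, 0.0, half, half)


def integrate(
    params: ModelParameters,
    init: SystemState,
    t_end: float = T_END,
    settings: SolverSettings | None = None,
) -> Trajectory:
    """Integrate the coupled system from ``init`` to ``t_end``.

    Non-negativity is enforced by clipping the state at zero inside the
    right-hand side and on the sampled output (clip magnitude is at the
    solver's absolute-tolerance scale).  Extinction clamping is event-based:
    the solver halts exactly where a population total crosses the threshold
    from above, that population is zeroed, and integration resumes.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end!r}")
    cfg = settings or SolverSettings()
    thr = cfg.extinction_threshold

    def rhs(t: float, y: np.ndarray) -> tuple[float, ...]:
        a = y[0] if y[0] > 0.0 else 0.0
        b = y[1] if y[1] > 0.0 else 0.0
        c = y[2] if y[2] > 0.0 else 0.0
        d = y[3] if y[3] > 0.0 else 0.0
        e = y[4] if y[4] > 0.0 else 0.0
        return _derivatives_raw(a, b, c, d, e, params)

    def plant_total_crossing(t: float, y: np.ndarray) -> float:
        return y[0] + y[1] + y[2] - thr

    def insect_total_crossing(t: float, y: np.ndarray) -> float:
        return y[3] + y[4] - thr

    for ev in (plant_total_crossing, insect_total_crossing):
        ev.terminal = True  # type: ignore[attr-defined]
        ev.direction = -1  # type: ignore[attr-defined]

    grid = np.linspace(0.0, t_end, cfg.n_samples)
    times: list[float] = [0.0]
    states: list[np.ndarray] = [np.asarray(init.as_tuple(), dtype=float)]
    events: list[tuple[float, str, str]] = []

    y = np.asarray(init.as_tuple(), dtype=float)
    plant_alive = True
    insect_alive = True

    def clamp(t_now: float) -> None:
        nonlocal y, plant_alive, insect_alive
        if plant_alive and y[0] + y[1] + y[2] < thr:
            y[0:3] = 0.0
            plant_alive = False
            events.append((t_now, "plant", "zeroed"))
        if insect_alive and y[3] + y[4] < thr:
            y[3:5] = 0.0
            insect_alive = False
            events.append((t_now, "insect", "zeroed"))

    clamp(0.0)
    states[0] = y.copy()
    t0 = 0.0
    while t0 < t_end:
        active = []
        if plant_alive:
            active.append(plant_total_crossing)
        if insect_alive:
            active.append(insect_total_crossing)
        sol = solve_ivp(
            rhs,
            (t0, t_end),
            y,
            method=cfg.method,
            rtol=cfg.rtol,
            atol=cfg.atol,
            dense_output=True,
            events=active or None,
        )
        if not sol.success:
            raise IntegrationError(f"integration failed: {sol.message}", float(sol.t[-1]))
        t_seg = float(sol.t[-1])
        inside = grid[(grid > t0) & (grid <= t_seg)]
        if inside.size:
            seg = sol.sol(inside).T
            times.extend(float(t) for t in inside)
            states.extend(np.clip(row, 0.0, None) for row in seg)
        y = np.clip(sol.y[:, -1], 0.0, None)
        fired = sol.status == 1
        if fired:
            # identify which total crossed; zero it and re-check the other
            labels = [
                ev is plant_total_crossing for ev in active
            ]
            for ev_idx, t_ev in enumerate(sol.t_events or []):
                if t_ev.size == 0:
                    continue
                if labels[ev_idx]:
                    y[0:3] = 0.0
                    plant_alive = False
                    events.append((t_seg, "plant", "zeroed"))
                else:
                    y[3:5] = 0.0
                    insect_alive = False
                    events.append((t_seg, "insect", "zeroed"))
            # replace the sample at the event time with the clamped state
            if times and times[-1] == t_seg:
                states[-1] = y.copy()
        t0 = t_seg
        if not fired:
            break

    if times[-1] < t_end:
        times.append(t_end)
        states.append(y.copy())
    return Trajectory(np.asarray(times), np.vstack(states), params, events)


def summarize(traj: Trajectory, window_fraction: float = WINDOW_FRACTION) -> SteadyStateSummary:
    """Time-weighted mean state over the trailing window.

    The window is [t_end·(1−window_fraction), t_end]; means are trapezoidal
    time averages, and the sex ratios are ratios of those means (stable when
    one sex is nearly absent).  A ratio whose denominator is below 1e−12 is
    reported as None.
    """
    if not (0.0 < window_fraction <= 1.0):
        raise ValueError(f"window_fraction must lie in (0, 1], got {window_fraction!r}")
    t = np.asarray(traj.times, dtype=float)
    x = np.asarray(traj.states, dtype=float)
    t_end = t[-1]
    t_start = t_end * (1.0 - window_fraction)

    mask = t >= t_start
    if not mask.any():
        raise ValueError("evaluation window contains no samples")
    tw = t[mask]
    xw = x[mask]
    if tw[0] > t_start and mask.argmax() > 0:
        # linear interpolation onto the exact window edge
        i = int(mask.argmax())
        frac = (t_start - t[i - 1]) / (t[i] - t[i - 1])
        edge = x[i - 1] + frac * (x[i] - x[i - 1])
        tw = np.concatenate(([t_start], tw))
        xw = np.vstack([edge, xw])

    span = tw[-1] - tw[0]
    if span > 0:
        means = np.trapezoid(xw, tw, axis=0) / span
    else:
        means = xw[-1]

    def ratio(male: float, female: float) -> float | None:
        total = male + female
        if total < RATIO_EPS:
            return None
        return male / total

    return SteadyStateSummary(
        mean_X_J=float(means[0]),
        mean_X_M=float(means[1]),
        mean_X_F=float(means[2]),
        mean_Y_M=float(means[3]),
        mean_Y_F=float(means[4]),
        plant_male_ratio=ratio(float(means[1]), float(means[2])),
        insect_male_ratio=ratio(float(means[3]), float(means[4])),
        window=(float(t_start), float(t_end)),
    )


def classify(summary: SteadyStateSummary, threshold: float = EXTINCTION_THRESHOLD) -> Outcome:
    """Map window-mean totals to the four-way outcome at ``threshold``."""
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold!r}")
    plant = summary.plant_total >= threshold
    insect = summary.insect_total >= threshold
    if plant and insect:
        return Outcome.COEXIST
    if plant:
        return Outcome.PLANT_ONLY
    if insect:
        return Outcome.INSECT_ONLY
    return Outcome.CO_EXTINCT


def run_to_outcome(
    params: ModelParameters,
    init: SystemState | None = None,
    t_end: float = T_END,
    window_fraction: float = WINDOW_FRACTION,
    threshold: float = EXTINCTION_THRESHOLD,
    settings: SolverSettings | None = None,
) -> tuple[SteadyStateSummary, Outcome]:
    """Protocol composition: integrate -> summarize -> classify."""
    if init is None:
        init = default_initial_state(params)
    traj = integrate(params, init, t_end=t_end, settings=settings)
    summary = summarize(traj, window_fraction=window_fraction)
    return summary, classify(summary, threshold=threshold)


def bistability_probe(
    params: ModelParameters,
    inits: Sequence[SystemState],
    t_end: float = T_END,
    settings: SolverSettings | None = None,
) -> list[Outcome]:
    """Run the protocol from each initial state; differing outcomes across
    the list flag alternative stable states (see :func:`is_bistable`)."""
    if len(inits) < 2:
        raise ValueError("bistability probe needs at least two initial states")
    return [
        run_to_outcome(params, init, t_end=t_end, settings=settings)[1]
        for init in inits
    ]


def is_bistable(outcomes: Sequence[Outcome]) -> bool:
    return len(set(outcomes)) > 1


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """CSV with columns t, X_J, X_M, X_F, Y_M, Y_F."""
    import pandas as pd

    frame = pd.DataFrame(traj.states, columns=["X_J", "X_M", "X_F", "Y_M", "Y_F"])
    frame.insert(0, "t", traj.times)
    frame.to_csv(path, index=False)


def write_summary_json(
    summary: SteadyStateSummary,
    outcome: Outcome,
    params: ModelParameters,
    path: str | Path,
    events: list[tuple[float, str, str]] | None = None,
) -> None:
    """Summary JSON: window means, ratios, outcome, full parameter echo."""
    payload = {
        "summary": summary.to_dict(),
        "outcome": outcome.value,
        "parameters": params.to_dict(),
    }
    if events is not None:
        payload["events"] = [list(e) for e in events]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
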