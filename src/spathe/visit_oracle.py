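"""Stochastic individual-based oracle for the lifetime visit statistics.

Simulates individual male fungus gnats making up to N categorical visits
(male plant / female plant / female insect) and tallies Q1, Q2 and P directly
from the realized sequences.  This is deliberately independent of the
combinatorial and closed-form expressions in :mod:`spathe.model_core` so it
can validate them.

Two modes:

* ``lethal=True`` (the trap-flower system): the sequence terminates at the
  first female-plant visit.  Q1 counts male-plant visits strictly before that
  death (a life with no female-plant visit transfers no pollen and counts 0);
  Q2 counts copulations before death, or over all N visits when no female
  plant is ever hit; P indicates whether the insect was trapped.
* ``lethal=False`` (release-after-deceit variant): all N visits are realized.
  Q1 counts male-plant visits made while still carrying pollen, i.e. before
  the first female-plant visit (all of them if none occurs); Q2 counts every
  copulation; P keeps its meaning as the probability of at least one
  female-plant visit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import VisitProbabilities, _check_n

__all__ = ["OracleEstimate", "simulate_visit_sequences"]


@dataclass(frozen=True)
class OracleEstimate:
    """Monte-Carlo estimates of (Q1, Q2, P) with standard errors."""

    Q1_hat: float
    Q2_hat: float
    P_hat: float
    se_Q1: float
    se_Q2: float
    se_P: float
    n_trials: int
    seed: int

    def __post_init__(self) -> None:
        for name in ("Q1_hat", "Q2_hat", "P_hat", "se_Q1", "se_Q2", "se_P"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not (0.0 <= self.P_hat <= 1.0):
            raise ValueError(f"P_hat must lie in [0, 1], got {self.P_hat!r}")
        if min(self.se_Q1, self.se_Q2, self.se_P) < 0.0:
            raise ValueError("standard errors must be >= 0")


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    n = values.size
    mean = float(values.mean())
    if n < 2:
        return mean, 0.0
    return mean, float(values.std(ddof=1) / math.sqrt(n))


def simulate_visit_sequences(
    probs: VisitProbabilities,
    N: int,
    n_trials: int,
    seed: int,
    lethal: bool = True,
) -> OracleEstimate:
    """Estimate (Q1, Q2, P) by simulating ``n_trials`` visit sequences.

    Each trial draws up to ``N`` independent categorical visit events with
    probabilities (p_M, p_F, p_Y).  Reproducible: one explicit generator per
    call, seeded with ``seed``.  With the all-zero (empty-world) probability
    triple every estimate is exactly 0.
    """
    _check_n(N)
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials!r}")
    if probs.is_empty_world:
        return OracleEstimate(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, n_trials, seed)

    rng = np.random.default_rng(seed)
    # visit codes: 0 = male plant, 1 = female plant (fatal), 2 = female insect
    u = rng.random((n_trials, N))
    codes = np.full((n_trials, N), 2, dtype=np.int8)
    codes[u < probs.p_M + probs.p_F] = 1
    codes[u < probs.p_M] = 0

    is_f = codes == 1
    hit_f = is_f.any(axis=1)
    # index of the first female-plant visit; N (one past the end) if none
    first_f = np.where(hit_f, is_f.argmax(axis=1), N)

    before_first_f = np.arange(N) < first_f[:, None]
    m_before = ((codes == 0) & before_first_f).sum(axis=1)
    y_before = ((codes == 2) & before_first_f).sum(axis=1)
    y_all = (codes == 2).sum(axis=1)

    if lethal:
        q1 = np.where(hit_f, m_before, 0)
        q2 = np.where(hit_f, y_before, y_all)
    else:
        q1 = m_before
        q2 = y_all

    q1_hat, se_q1 = _mean_se(q1.astype(float))
    q2_hat, se_q2 = _mean_se(q2.astype(float))
    p_hat, se_p = _mean_se(hit_f.astype(float))
    return OracleEstimate(q1_hat, q2_hat, p_hat, se_q1, se_q2, se_p, n_trials, seed)
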