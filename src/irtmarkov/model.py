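"""Core probability mathematics of the IRT-mCTMM.

The model couples a graded-response item-response-theory (IRT) model with a
minimal continuous-time Markov model (mCTMM) per questionnaire item:

* Each item ``j`` has a discrimination ``a_j > 0`` and ordered difficulties
  ``b_{j,1} <= ... <= b_{j,K-1}``.  Given a subject's latent disease severity
  ``D``, the cumulative probability of scoring at or above category ``k`` is
  logistic, ``P(Y >= k) = expit(a_j * (D - b_{j,k}))``, and exact-category
  probabilities follow by differencing (the steady-state distribution).
* ``D`` drifts linearly in time, ``D_i(t) = D_{i,0} + slope_i * t / 365``
  (slope stored per year, time in days).
* Serial dependence between daily scores of one item is a birth-death
  continuous-time Markov chain over the score categories whose stationary law
  is the steady-state IRT distribution and whose single free dependence
  parameter is the mean equilibrium time MET: for every adjacent category
  pair the up and down rates satisfy ``lambda_up + lambda_down = 1 / MET``
  with detailed balance fixing their ratio.

Pure computation only; no file I/O and no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import expm
from scipy.special import expit

__all__ = [
    "ItemSpec",
    "PopulationParams",
    "SubjectEffects",
    "latent_severity",
    "prob_at_or_above",
    "steady_state_probs",
    "rate_constants",
    "build_generator",
    "transition_kernel",
    "met_at_time",
    "stationary_distribution",
    "PROB_FLOOR",
]

#: Floor applied to steady-state probabilities before forming the p_k/p_{k+1}
#: ratios of the rate-constant equations; logistic probabilities are never
#: exactly 0 but can underflow at extreme latent severities.
PROB_FLOOR = 1e-12

DAYS_PER_YEAR = 365.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ItemSpec:
    """IRT parameters of one ordinal questionnaire item.

    Parameters
    ----------
    item_id
        Integer label of the item (1..14 for the standard catalogue).
    n_categories
        Number of ordered response categories K (4 or 5); scores are 0..K-1.
    a
        Discrimination (slope) parameter, dimensionless, > 0.
    b
        Difficulty cut-points ``(b_1, ..., b_{K-1})`` on the latent scale,
        non-decreasing.
    """

    item_id: int
    n_categories: int
    a: float
    b: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "b", tuple(float(x) for x in self.b))
        if self.n_categories < 2:
            raise ValueError("an item needs at least 2 categories")
        if len(self.b) != self.n_categories - 1:
            raise ValueError(
                f"item {self.item_id}: expected {self.n_categories - 1} "
                f"difficulties, got {len(self.b)}"
            )
        if not self.a > 0:
            raise ValueError(f"item {self.item_id}: discrimination must be > 0")
        if any(b2 < b1 for b1, b2 in zip(self.b, self.b[1:])):
            raise ValueError(f"item {self.item_id}: difficulties must be non-decreasing")

    @property
    def max_score(self) -> int:
        return self.n_categories - 1


@dataclass(frozen=True)
class SubjectEffects:
    """One subject's realized random effects.

    ``d0`` is the baseline latent severity (population law N(0,1)), ``slope``
    the individual progression rate in latent units per year, and ``eta_met``
    the log-scale MET deviation: ``MET_i(t) = MET_pop(t) * exp(eta_met)``.
    """

    d0: float
    slope: float
    eta_met: float = 0.0


@dataclass(frozen=True)
class PopulationParams:
    """Population parameters: item catalogue, trajectory and MET structure.

    ``met_mode`` is ``"shared"`` (one MET for all items) or ``"per_item"``
    (``met0`` is then a per-item vector aligned with ``items``).
    ``met_time_mode`` selects the time profile of the population MET:

    * ``"constant"``: MET_pop(t) = met0
    * ``"linear"``:   MET_pop(t) = met0 + met_tslope * t
    * ``"power"``:    MET_pop(t) = met0 * (1 + t) ** met_tslope

    ``met_tslope`` is therefore a slope in days/day for the linear mode and a
    dimensionless exponent for the power mode.  The baseline latent-severity
    standard deviation is fixed at 1 for identifiability.
    """

    items: tuple[ItemSpec, ...]
    slope_mean: float = 0.0
    slope_sd: float = 0.0
    met0: float | tuple[float, ...] = 1.0
    met_tslope: float = 0.0
    met_iiv_sd: float = 0.0
    met_mode: str = "shared"
    met_time_mode: str = "constant"
    d0_sd: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if self.met_mode not in ("shared", "per_item"):
            raise ValueError(f"unknown met_mode {self.met_mode!r}")
        if self.met_time_mode not in ("constant", "linear", "power"):
            raise ValueError(f"unknown met_time_mode {self.met_time_mode!r}")
        if self.d0_sd not in (0.0, 1.0):
            # fixed at 1 for identifiability; 0 only for degenerate checks
            raise ValueError("d0_sd is fixed at 1 (0 allowed to switch IIV off)")
        if self.met_mode == "per_item":
            met0 = tuple(float(m) for m in np.atleast_1d(self.met0))
            if len(met0) != len(self.items):
                raise ValueError("per_item met_mode needs one met0 per item")
            object.__setattr__(self, "met0", met0)
        else:
            object.__setattr__(self, "met0", float(np.asarray(self.met0).reshape(())))
        for m in np.atleast_1d(self.met0):
            if not m > 0:
                raise ValueError("met0 must be > 0")
        if self.slope_sd < 0 or self.met_iiv_sd < 0:
            raise ValueError("variability SDs must be >= 0")

    @property
    def n_items(self) -> int:
        return len(self.items)

    def item_index(self, item_id: int) -> int:
        for i, it in enumerate(self.items):
            if it.item_id == item_id:
                return i
        raise KeyError(f"unknown item_id {item_id}")

    def met0_for(self, item_index: int) -> float:
        if self.met_mode == "per_item":
            return self.met0[item_index]
        return self.met0

    def with_items(self, items: Sequence[ItemSpec]) -> "PopulationParams":
        return replace(self, items=tuple(items))


# ---------------------------------------------------------------------------
# latent trajectory and MET profile
# ---------------------------------------------------------------------------


def latent_severity(effects: SubjectEffects, t):
    """Latent disease severity D_i(t) = d0 + slope * t / 365 (t in days)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = effects.d0 + effects.slope * t / DAYS_PER_YEAR
    return float(out) if out.ndim == 0 else out


def met_population(pop: PopulationParams, t, item_index: int = 0):
    """Population MET profile (days) at study time ``t`` for one item."""
    t = np.asarray(t, dtype=float)
    met0 = pop.met0_for(item_index)
    if pop.met_time_mode == "constant":
        met = np.broadcast_to(np.asarray(met0, dtype=float), t.shape).copy()
    elif pop.met_time_mode == "linear":
        met = met0 + pop.met_tslope * t
    else:  # power
        met = met0 * np.power(1.0 + t, pop.met_tslope)
    return met


def met_at_time(pop: PopulationParams, effects: SubjectEffects, t, item_id=None):
    """Individual MET_i(t) = MET_pop(t) * exp(eta_met), in days.

    Raises if the resulting MET is non-positive anywhere (invalid parameter
    region, e.g. a linear time slope driving MET below zero inside the study
    window).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    idx = 0 if item_id is None else pop.item_index(item_id)
    met = met_population(pop, t, idx) * np.exp(effects.eta_met)
    if np.any(met <= 0):
        raise ValueError("MET must stay positive over the study window")
    return float(met) if met.ndim == 0 else met


# ---------------------------------------------------------------------------
# graded-response curves
# ---------------------------------------------------------------------------


def prob_at_or_above(item: ItemSpec, D: float) -> np.ndarray:
    """Cumulative probabilities P(Y >= k), k = 1..K-1, at severity ``D``.

    Element ``k-1`` is ``expit(a * (D - b_k))``; the vector is non-increasing
    because the difficulties are ordered.
    """
    b = np.asarray(item.b, dtype=float)
    return expit(item.a * (float(D) - b))


def steady_state_probs(item: ItemSpec, D: float) -> np.ndarray:
    """Exact-category probabilities P(Y = k), k = 0..K-1 (sums to 1).

    This is both the single-observation IRT law and the stationary
    distribution of the item's Markov chain.
    """
    c = prob_at_or_above(item, D)
    p = np.empty(item.n_categories)
    p[0] = 1.0 - c[0]
    p[1:-1] = c[:-1] - c[1:]
    p[-1] = c[-1]
    return p


# ---------------------------------------------------------------------------
# MET <-> rate-constant reparameterisation and the generator
# ---------------------------------------------------------------------------


def rate_constants(pss: np.ndarray, met: float) -> tuple[np.ndarray, np.ndarray]:
    """Adjacent-pair transition rates implied by (steady state, MET).

    For each adjacent category pair ``k, k+1``::

        lambda_up[k]   = 1 / (MET * (1 + p_k / p_{k+1}))
        lambda_down[k] = lambda_up[k] * p_k / p_{k+1}

    so that ``lambda_up[k] + lambda_down[k] = 1 / MET`` for every pair and
    detailed balance ``p_k * lambda_up[k] = p_{k+1} * lambda_down[k]`` holds.
    Probabilities are floored at ``PROB_FLOOR`` before the ratio is formed.
    """
    if not met > 0:
        raise ValueError("MET must be > 0")
    p = np.maximum(np.asarray(pss, dtype=float), PROB_FLOOR)
    ratio = p[:-1] / p[1:]
    lam_up = 1.0 / (met * (1.0 + ratio))
    lam_down = lam_up * ratio
    return lam_up, lam_down


def build_generator(pss: np.ndarray, met: float) -> np.ndarray:
    """Tridiagonal birth-death generator Q (units 1/day) with stationary law
    ``pss``.

    Rows sum to zero; only adjacent-category transitions have non-zero rates,
    so a 4-category item simply has no rates touching a fifth state.
    """
    lam_up, lam_down = rate_constants(pss, met)
    K = len(pss)
    Q = np.zeros((K, K))
    idx = np.arange(K - 1)
    Q[idx, idx + 1] = lam_up
    Q[idx + 1, idx] = lam_down
    Q[np.arange(K), np.arange(K)] = -Q.sum(axis=1)
    return Q


def transition_kernel(Q: np.ndarray, dt: float) -> np.ndarray:
    """Transition probability matrix ``P = expm(Q * dt)`` over ``dt`` days.

    ``P[r, c]`` is the probability of score ``c`` after ``dt`` days given
    score ``r`` now; this solves the forward probability ODE system from each
    unit-vector initial condition (the post-observation probability reset).

    Birth-death generators built by :func:`build_generator` are reversible,
    so the exponential is evaluated through the symmetrized spectral form
    (numerically exact even for ``dt >> MET``); a non-reversible ``Q`` falls
    back to scipy's expm.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    Q = np.asarray(Q, dtype=float)
    pi = stationary_distribution(Q)
    if np.all(pi > 0) and np.allclose(
        pi[:, None] * Q, (pi[:, None] * Q).T, rtol=1e-8, atol=1e-13
    ):
        sp = np.sqrt(pi)
        M = (sp[:, None] / sp[None, :]) * Q * dt
        w, V = np.linalg.eigh(0.5 * (M + M.T))
        E = (V * np.exp(w)) @ V.T
        P = (sp[None, :] / sp[:, None]) * E
    else:
        P = expm(Q * float(dt))
    # clip tiny negative round-off and renormalise rows
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    return P


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary law of a generator via the null space of Q^T (oracle use)."""
    Q = np.asarray(Q, dtype=float)
    _, _, vt = np.linalg.svd(Q.T)
    v = vt[-1]
    v = np.abs(v)
    return v / v.sum()
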