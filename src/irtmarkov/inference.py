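"""Marginal likelihood and parameter estimation for the IRT-mCTMM.

The joint likelihood of one subject conditions on a 3-dimensional random
effect vector (baseline severity ``d0``, progression ``slope``, log-MET
deviation ``eta_met``), assumed mutually independent:

* per item, the first observed score contributes the steady-state
  probability at the severity of that day;
* every later observation contributes the transition-kernel entry from the
  previous score over the elapsed day gap, with the generator built from the
  steady state and MET at the left endpoint of the interval (the probability
  vector is reset to a point mass at each observation).

The marginal likelihood integrates the conditional likelihood over the
population law of the random effects, by default with a Laplace
approximation (inner mode by Newton iterations, log-determinant of the
negative Hessian by finite differences of the analytic inner gradient);
adaptive Gauss-Hermite quadrature is available as a slower, more accurate
oracle.  The objective is reported as OFV = -2 log-likelihood and nested
models are compared on the chi-square scale of their OFV difference.

Gradient note: the gradient of the Laplace objective with respect to the
population parameters combines the analytic conditional-likelihood gradient
at the inner mode (envelope theorem) with the explicit parameter dependence
of the log-determinant term, evaluated as directional second differences of
that analytic gradient along the inner-Hessian eigenvectors; only the small
coupling through the inner-mode shift is omitted.  Objective *values* are
always exact Laplace, and an optional finite-difference ``refine`` phase is
available when an optimum must be pinned below ~0.1 OFV units.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, roots_hermite

from . import _spectral
from .model import (
    DAYS_PER_YEAR,
    PROB_FLOOR,
    ItemSpec,
    PopulationParams,
    SubjectEffects,
)
from .simulate import DiaryDataset

__all__ = [
    "FitResult",
    "conditional_loglik",
    "marginal_loglik",
    "fit",
    "compare_models",
    "init_from_collapsed_fits",
]

_MIN_B_GAP = 1e-3  # smallest admissible difficulty increment on the fit scale


# ---------------------------------------------------------------------------
# packed long-format data
# ---------------------------------------------------------------------------


@dataclass
class _Packed:
    """Flat per-observation arrays sorted by (subject, item, day)."""

    subj: np.ndarray        # subject index 0..n_subj-1
    item: np.ndarray        # item index into the catalogue
    day: np.ndarray         # observation day (float)
    t_eval: np.ndarray      # parameter-evaluation time (left interval endpoint)
    score: np.ndarray
    prev: np.ndarray        # previous score (-1 for first observations)
    dt: np.ndarray          # elapsed days since previous observation (0 first)
    is_first: np.ndarray
    n_subj: int
    subject_ids: np.ndarray
    items: tuple[ItemSpec, ...]

    @property
    def n_obs(self) -> int:
        return len(self.subj)


def _pack(dataset: DiaryDataset, interval_eval: str = "start") -> _Packed:
    df = dataset.records.sort_values(["subject_id", "item_id", "day"], kind="stable")
    sids = df["subject_id"].unique()
    sidx = df["subject_id"].map({s: i for i, s in enumerate(sids)}).to_numpy()
    iidx = df["item_id"].map({it.item_id: i for i, it in enumerate(dataset.items)}).to_numpy()
    day = df["day"].to_numpy(dtype=float)
    score = df["score"].to_numpy()
    chain = sidx * (len(dataset.items) + 1) + iidx
    new_chain = np.empty(len(df), dtype=bool)
    new_chain[0] = True
    new_chain[1:] = chain[1:] != chain[:-1]
    prev = np.empty_like(score)
    prev[0] = -1
    prev[1:] = score[:-1]
    prev[new_chain] = -1
    dt = np.zeros(len(df))
    dt[1:] = day[1:] - day[:-1]
    dt[new_chain] = 0.0
    if interval_eval == "start":
        t_eval = np.where(new_chain, day, day - dt)
    elif interval_eval == "midpoint":
        t_eval = np.where(new_chain, day, day - 0.5 * dt)
    else:
        raise ValueError(f"unknown interval_eval {interval_eval!r}")
    return _Packed(
        subj=sidx,
        item=iidx,
        day=day,
        t_eval=t_eval,
        score=score,
        prev=prev,
        dt=dt,
        is_first=new_chain,
        n_subj=len(sids),
        subject_ids=sids,
        items=dataset.items,
    )


def _item_tables(items: Sequence[ItemSpec]):
    Kmax = max(it.n_categories for it in items)
    a = np.array([it.a for it in items])
    b = np.full((len(items), Kmax - 1), np.inf)
    for i, it in enumerate(items):
        b[i, : it.n_categories - 1] = it.b
    K = np.array([it.n_categories for it in items])
    return a, b, K, Kmax


# ---------------------------------------------------------------------------
# conditional log-likelihood core (vectorised, with analytic gradients)
# ---------------------------------------------------------------------------


def _met_pop_obs(pop: PopulationParams, t: np.ndarray, item: np.ndarray) -> np.ndarray:
    met0 = np.array([pop.met0_for(i) for i in range(pop.n_items)])[item]
    if pop.met_time_mode == "constant":
        return met0
    if pop.met_time_mode == "linear":
        return met0 + pop.met_tslope * t
    return met0 * (1.0 + t) ** pop.met_tslope


def _core_loglik(
    packed: _Packed,
    pop: PopulationParams,
    eff: np.ndarray,
    eff_idx: np.ndarray,
    need_grad: bool = False,
):
    """Conditional log-likelihood terms for every observation.

    ``eff`` is an (m, 3) array of natural-unit effects (d0, slope, eta_met)
    and ``eff_idx`` maps observations to its rows (the subject index for a
    plain evaluation; an expanded index for quadrature).  Returns per-row
    log-likelihood sums and, when requested, analytic gradients with respect
    to the effects and the population parameters.
    """
    a_it, b_it, K_it, Kmax = _item_tables(pop.items)
    item = packed.item
    a = a_it[item]
    b = b_it[item]
    K = K_it[item]
    t = packed.t_eval
    d0 = eff[eff_idx, 0]
    slope = eff[eff_idx, 1]
    eta = eff[eff_idx, 2]
    D = d0 + slope * t / DAYS_PER_YEAR

    with np.errstate(invalid="ignore"):
        z = a[:, None] * (D[:, None] - b)
    z = np.where(np.isinf(b), -np.inf, z)
    c = expit(z)  # (n_obs, Kmax-1), padded thresholds give 0
    pi_raw = np.empty((packed.n_obs, Kmax))
    pi_raw[:, 0] = 1.0 - c[:, 0]
    pi_raw[:, 1:-1] = c[:, :-1] - c[:, 1:]
    pi_raw[:, -1] = c[:, -1]
    np.clip(pi_raw, 0.0, None, out=pi_raw)
    valid = np.arange(Kmax)[None, :] < K[:, None]
    pi = np.where(valid, np.maximum(pi_raw, PROB_FLOOR), 0.0)

    met_pop = _met_pop_obs(pop, t, item)
    if np.any(met_pop[~packed.is_first] <= 0):
        return None  # invalid parameter region (non-positive MET)
    met = met_pop * np.exp(eta)

    logp = np.zeros(packed.n_obs)
    first = packed.is_first
    rows_f = np.nonzero(first)[0]
    p_first = pi_raw[rows_f, packed.score[rows_f]]
    # clamp keeps the surface finite for the optimiser; 1e-300 is an
    # effective -inf (log ~ -690) that gradients can still escape from
    logp[rows_f] = np.log(np.maximum(p_first, 1e-300))

    dll_dc = np.zeros((packed.n_obs, Kmax - 1)) if need_grad else None
    dll_dlogmet = np.zeros(packed.n_obs) if need_grad else None
    if need_grad:
        s_f = packed.score[rows_f]
        inv = np.where(p_first > 0, 1.0 / np.maximum(p_first, 1e-300), 0.0)
        has_lo = s_f >= 1
        dll_dc[rows_f[has_lo], s_f[has_lo] - 1] += inv[has_lo]
        has_hi = s_f <= K[rows_f] - 2
        dll_dc[rows_f[has_hi], s_f[has_hi]] -= inv[has_hi]

    trans = ~first
    for Kv in np.unique(K[trans]):
        g = np.nonzero(trans & (K == Kv))[0]
        res = _spectral.kernel_entry_terms(
            pi[g][:, :Kv], met[g], packed.dt[g], packed.prev[g], packed.score[g],
            need_grad=need_grad,
        )
        logp[g] = res["logp"]
        if need_grad:
            dpi = res["dlogp_dpi"]
            # floor clamp: no sensitivity where the raw probability was clipped
            clamped = pi_raw[g][:, :Kv] < PROB_FLOOR
            dpi = np.where(clamped, 0.0, dpi)
            # chain pi -> cumulative c:  pi_k = c_k - c_{k+1} (c_0 = 1)
            dc = dpi[:, 1:] - dpi[:, :-1]
            dll_dc[g[:, None], np.arange(Kv - 1)[None, :]] = dc
            dll_dlogmet[g] = res["dlogp_dlogmet"]

    out = {"logp": logp, "met_pop": met_pop}
    if not need_grad:
        return out

    dcdz = c * (1.0 - c)
    dll_dz = dll_dc * dcdz
    dll_dD = a * dll_dz.sum(axis=1)
    out["dll_dD"] = dll_dD
    out["dll_dlogmet"] = dll_dlogmet
    out["dll_dz"] = dll_dz
    out["D"] = D
    # per-effect-row gradients
    m = len(eff)
    g_eff = np.zeros((m, 3))
    np.add.at(g_eff[:, 0], eff_idx, dll_dD)
    np.add.at(g_eff[:, 1], eff_idx, dll_dD * t / DAYS_PER_YEAR)
    np.add.at(g_eff[:, 2], eff_idx, dll_dlogmet)
    out["grad_eff"] = g_eff
    return out


def _theta_item_grads(packed: _Packed, pop: PopulationParams, core: dict):
    """Accumulate gradients w.r.t. a_j, b_jk and the MET parameters."""
    a_it, b_it, K_it, Kmax = _item_tables(pop.items)
    item = packed.item
    dll_dz = core["dll_dz"]
    D = core["D"]
    b = b_it[item]
    with np.errstate(invalid="ignore"):
        Dmb = np.where(np.isinf(b), 0.0, D[:, None] - b)
    n_items = len(pop.items)
    da = np.zeros(n_items)
    np.add.at(da, item, (dll_dz * Dmb).sum(axis=1))
    db = np.zeros((n_items, Kmax - 1))
    np.add.at(db, item, -a_it[item][:, None] * dll_dz)

    t = packed.t_eval
    met_pop = core["met_pop"]
    dlm = core["dll_dlogmet"]
    if pop.met_time_mode == "constant":
        dmet0_obs = dlm / met_pop
        dts_obs = np.zeros_like(dlm)
    elif pop.met_time_mode == "linear":
        dmet0_obs = dlm / met_pop
        dts_obs = dlm * t / met_pop
    else:  # power
        met0 = np.array([pop.met0_for(i) for i in range(pop.n_items)])[item]
        dmet0_obs = dlm / met0
        dts_obs = dlm * np.log1p(t)
    if pop.met_mode == "per_item":
        dmet0 = np.zeros(n_items)
        np.add.at(dmet0, item, dmet0_obs)
    else:
        dmet0 = dmet0_obs.sum()
    return {"da": da, "db": db, "dmet0": dmet0, "dmet_tslope": dts_obs.sum()}


# ---------------------------------------------------------------------------
# public conditional likelihood
# ---------------------------------------------------------------------------


def conditional_loglik(
    dataset: DiaryDataset,
    pop: PopulationParams,
    effects: SubjectEffects | Sequence[SubjectEffects],
    interval_eval: str = "start",
):
    """Conditional log-likelihood given realized subject effects.

    With a single :class:`SubjectEffects` (single-subject dataset) returns a
    float; with a sequence (one per subject, in subject-id order) returns the
    per-subject array.  A transition that has zero probability even under the
    floored steady state reports ``-inf`` rather than raising.
    """
    packed = _pack(dataset, interval_eval)
    if isinstance(effects, SubjectEffects):
        effects = [effects]
    if len(effects) != packed.n_subj:
        raise ValueError("need one SubjectEffects per subject")
    eff = np.array([[e.d0, e.slope, e.eta_met] for e in effects])
    core = _core_loglik(packed, pop, eff, packed.subj)
    if core is None:
        raise ValueError("MET must stay positive over the observation window")
    per_subj = np.zeros(packed.n_subj)
    np.add.at(per_subj, packed.subj, core["logp"])
    return float(per_subj[0]) if len(effects) == 1 else per_subj


# ---------------------------------------------------------------------------
# random-effect standardisation and the Laplace engine
# ---------------------------------------------------------------------------


def _active_dims(pop: PopulationParams) -> list[int]:
    dims = []
    if pop.d0_sd > 0:
        dims.append(0)
    if pop.slope_sd > 0:
        dims.append(1)
    if pop.met_iiv_sd > 0:
        dims.append(2)
    return dims


def _eta_to_eff(pop: PopulationParams, eta: np.ndarray, dims: list[int]) -> np.ndarray:
    """Map standardized N(0,1) effects to natural units (n, 3)."""
    n = len(eta)
    eff = np.zeros((n, 3))
    eff[:, 1] = pop.slope_mean
    scales = _eta_scales(pop)
    for j, d in enumerate(dims):
        eff[:, d] += scales[d] * eta[:, j]
    return eff


def _eta_scales(pop: PopulationParams) -> np.ndarray:
    return np.array([pop.d0_sd, pop.slope_sd, pop.met_iiv_sd])


def _replicate_packed(packed: _Packed, m: int) -> _Packed:
    """Tile the observation arrays ``m`` times (pseudo-subject expansion)."""
    return _Packed(
        subj=np.tile(packed.subj, m),
        item=np.tile(packed.item, m),
        day=np.tile(packed.day, m),
        t_eval=np.tile(packed.t_eval, m),
        score=np.tile(packed.score, m),
        prev=np.tile(packed.prev, m),
        dt=np.tile(packed.dt, m),
        is_first=np.tile(packed.is_first, m),
        n_subj=packed.n_subj * m,
        subject_ids=np.arange(packed.n_subj * m),
        items=packed.items,
    )


class _LaplaceState:
    """Warm-start cache for the inner modes across outer iterations."""

    def __init__(self, n_subj: int, n_dims: int):
        self.eta = np.zeros((n_subj, n_dims))


def _inner_newton(
    packed: _Packed,
    pop: PopulationParams,
    eta0: np.ndarray,
    dims: list[int],
    tol: float = 5e-5,
    max_iter: int = 40,
    fd_step: float = 1e-4,
):
    """Batched Newton maximisation of h(eta) = loglik(eff(eta)) - ||eta||^2/2.

    Returns the modes, h at the modes, the per-subject negative Hessians
    (positive definite, by eigenvalue clipping if needed) and the analytic
    conditional-likelihood gradients at the modes.
    """
    na = len(dims)
    scales = _eta_scales(pop)[dims]
    eta = eta0.copy()

    def h_only(eta_mat):
        eff = _eta_to_eff(pop, eta_mat, dims)
        core = _core_loglik(packed, pop, eff, packed.subj)
        if core is None:
            return None
        ll = np.zeros(packed.n_subj)
        np.add.at(ll, packed.subj, core["logp"])
        return ll - 0.5 * (eta_mat**2).sum(axis=1)

    def h_and_grad(eta_mat):
        eff = _eta_to_eff(pop, eta_mat, dims)
        core = _core_loglik(packed, pop, eff, packed.subj, need_grad=True)
        if core is None:
            return None, None, None
        ll = np.zeros(packed.n_subj)
        np.add.at(ll, packed.subj, core["logp"])
        g = core["grad_eff"][:, dims] * scales[None, :] - eta_mat
        return ll - 0.5 * (eta_mat**2).sum(axis=1), g, core

    n_subj = packed.n_subj
    scales_full = _eta_scales(pop)

    def fd_neg_hessian(eta_mat, g_base):
        # one stacked core evaluation for all na forward perturbations
        stacked = np.repeat(eta_mat[None, :, :], na, axis=0)
        for j in range(na):
            stacked[j, :, j] += fd_step
        eta_big = stacked.reshape(na * n_subj, na)
        eff = _eta_to_eff(pop, eta_big, dims)
        big_idx = (np.arange(na)[:, None] * n_subj + packed.subj[None, :]).ravel()
        big = _replicate_packed(packed, na)
        core_p = _core_loglik(big, pop, eff, big_idx, need_grad=True)
        gp = core_p["grad_eff"][:, dims] * scales_full[dims][None, :]
        gp = gp.reshape(na, n_subj, na) - stacked
        H = (gp - g_base[None, :, :]).transpose(1, 2, 0) / fd_step  # (n, grad, j)
        return -0.5 * (H + H.transpose(0, 2, 1))

    h, g, core = h_and_grad(eta)
    if h is None:
        return None
    Hmat = None
    H_eta = None
    for it in range(max_iter):
        if np.max(np.abs(g)) < tol:
            break
        # the curvature changes slowly: refresh the FD Hessian only
        # periodically and use it as a Newton preconditioner in between
        if Hmat is None or it % 4 == 0:
            Hmat = fd_neg_hessian(eta, g)
            H_eta = eta.copy()
            w, V = np.linalg.eigh(Hmat)
            w = np.maximum(w, 1e-6)
            Hfac = (w, V)
        w, V = Hfac
        step = np.einsum("nij,nj->ni", V, np.einsum("nij,ni->nj", V, g) / w)
        norm = np.linalg.norm(step, axis=1, keepdims=True)
        step = np.where(norm > 4.0, step * 4.0 / norm, step)
        # cheap (gradient-free) backtracking on subjects whose h decreases
        h_new = h_only(eta + step)
        for _bt in range(8):
            worse = h_new < h - 1e-10
            if not worse.any():
                break
            step[worse] *= 0.5
            h_new = h_only(eta + step)
        eta = eta + step
        h, g, core = h_and_grad(eta)
    # curvature at the mode (reused if the mode barely moved since computed)
    if Hmat is None or np.max(np.abs(eta - H_eta)) > 1e-3:
        H = fd_neg_hessian(eta, g)
    else:
        H = Hmat
    w, V = np.linalg.eigh(H)
    w = np.maximum(w, 1e-8)
    logdet = np.log(w).sum(axis=1)
    # exact derivative of logdet(H) w.r.t. the log IIV scale of each active
    # dimension, holding the conditional curvature fixed:
    # H = I + S C S  =>  d logdet / d log sd_j = 2 (1 - [H^-1]_jj)
    hinv_diag = np.einsum("njk,nk->nj", V**2, 1.0 / w)
    converged = np.max(np.abs(g), axis=1) < 10 * tol
    return {
        "eta": eta,
        "h": h,
        "logdet": logdet,
        "dlogdet_dlogsd": 2.0 * (1.0 - hinv_diag),
        "H_eigs": (w, V),
        "core": core,
        "grad_eff": core["grad_eff"],
        "converged": converged,
    }


def _laplace_loglik(packed, pop, state: _LaplaceState | None = None, **kw):
    dims = _active_dims(pop)
    na = len(dims)
    if packed.n_subj == 0:
        raise ValueError("no subjects")
    if na == 0:
        # degenerate integral: the marginal is the conditional at the means
        eff = _eta_to_eff(pop, np.zeros((packed.n_subj, 0)), dims)
        core = _core_loglik(packed, pop, eff, packed.subj, need_grad=True)
        if core is None:
            return None
        ll = np.zeros(packed.n_subj)
        np.add.at(ll, packed.subj, core["logp"])
        return {
            "eta": np.zeros((packed.n_subj, 0)),
            "h": ll,
            "logdet": np.zeros(packed.n_subj),
            "H_eigs": (np.ones((packed.n_subj, 0)), np.ones((packed.n_subj, 0, 0))),
            "core": core,
            "grad_eff": core["grad_eff"],
            "converged": np.ones(packed.n_subj, dtype=bool),
            "per_subject": ll,
            "dims": dims,
        }
    eta0 = state.eta if state is not None and state.eta.shape == (packed.n_subj, na) else np.zeros((packed.n_subj, na))
    sol = _inner_newton(packed, pop, eta0, dims, **kw)
    if sol is None:
        return None
    if state is not None:
        state.eta = sol["eta"]
    per_subject = sol["h"] - 0.5 * sol["logdet"]
    sol["per_subject"] = per_subject
    sol["dims"] = dims
    return sol


def _aghq_loglik(packed, pop, n_nodes: int = 15):
    """Adaptive Gauss-Hermite marginal log-likelihood (per-subject array)."""
    dims = _active_dims(pop)
    na = len(dims)
    sol = _laplace_loglik(packed, pop)
    if sol is None:
        raise ValueError("invalid parameters for quadrature")
    if na == 0:
        return sol["per_subject"]
    x, w = roots_hermite(n_nodes)
    grids = np.meshgrid(*([x] * na), indexing="ij")
    z = np.stack([g.ravel() for g in grids], axis=1)          # (n_q, na)
    lw = np.sum(
        np.stack(np.meshgrid(*([np.log(w)] * na), indexing="ij"), axis=-1).reshape(-1, na),
        axis=1,
    )
    n_q = len(z)

    wH, VH = sol["H_eigs"]
    # C = H^{-1/2} (symmetric): eta = eta_hat + sqrt(2) C z
    C = np.einsum("nij,nj,nkj->nik", VH, 1.0 / np.sqrt(wH), VH)
    eta_hat = sol["eta"]
    n_subj = packed.n_subj
    etas = eta_hat[:, None, :] + np.sqrt(2.0) * np.einsum("nij,qj->nqi", C, z)

    # expand observations across quadrature nodes
    eff_rows = etas.reshape(n_subj * n_q, -1)
    eff = _eta_to_eff(pop, eff_rows, dims)
    # pseudo-subject index: subject-major, node-minor
    big_idx = (packed.subj[:, None] * n_q + np.arange(n_q)[None, :]).ravel()
    big = _Packed(
        subj=np.repeat(packed.subj, n_q),
        item=np.repeat(packed.item, n_q),
        day=np.repeat(packed.day, n_q),
        t_eval=np.repeat(packed.t_eval, n_q),
        score=np.repeat(packed.score, n_q),
        prev=np.repeat(packed.prev, n_q),
        dt=np.repeat(packed.dt, n_q),
        is_first=np.repeat(packed.is_first, n_q),
        n_subj=n_subj * n_q,
        subject_ids=np.arange(n_subj * n_q),
        items=packed.items,
    )
    core = _core_loglik(big, pop, eff, big_idx)
    ll = np.zeros(n_subj * n_q)
    np.add.at(ll, big_idx, core["logp"])
    h = ll.reshape(n_subj, n_q) - 0.5 * (eff_rows.reshape(n_subj, n_q, -1) ** 2).sum(axis=2)
    # log L = -(na/2) log(2 pi) + (na/2) log 2 + logdet C + logsumexp(...)
    arg = h + (z**2).sum(axis=1)[None, :] + lw[None, :]
    mx = arg.max(axis=1)
    lse = mx + np.log(np.exp(arg - mx[:, None]).sum(axis=1))
    logdetC = -0.5 * np.log(wH).sum(axis=1)
    return lse + logdetC + 0.5 * na * (np.log(2.0) - np.log(2.0 * np.pi))


def marginal_loglik(
    dataset: DiaryDataset,
    pop: PopulationParams,
    method: str = "laplace",
    n_nodes: int = 15,
    per_subject: bool = False,
):
    """Marginal log-likelihood of the dataset under the population model.

    ``method="laplace"`` uses the Laplace approximation; ``method="aghq"``
    adaptive Gauss-Hermite quadrature with ``n_nodes`` nodes per active
    random-effect dimension (>= 7 recommended).  With every IIV standard
    deviation equal to zero the marginal equals the conditional likelihood at
    the population means.
    """
    packed = _pack(dataset)
    if method == "laplace":
        sol = _laplace_loglik(packed, pop)
        if sol is None:
            raise ValueError("MET must stay positive over the observation window")
        ps = sol["per_subject"]
    elif method == "aghq":
        if n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        ps = _aghq_loglik(packed, pop, n_nodes)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ps if per_subject else float(ps.sum())


# ---------------------------------------------------------------------------
# population-parameter packing for optimisation
# ---------------------------------------------------------------------------


class _ThetaMap:
    """Bijection between free population parameters and an unconstrained
    vector.

    Items use log-discrimination and an ordered parameterisation of the
    difficulties (first cut-point raw, positive increments on the log scale);
    met0, the IIV standard deviations use log transforms; slope_mean and the
    MET time coefficient are unconstrained.
    """

    def __init__(self, pop: PopulationParams, fixed: dict | None = None):
        self.template = pop
        self.fixed = dict(fixed or {})
        self.names: list[str] = []
        for it in pop.items:
            self.names.append(f"log_a[{it.item_id}]")
            self.names.append(f"b1[{it.item_id}]")
            for k in range(2, it.n_categories):
                self.names.append(f"log_db{k}[{it.item_id}]")
        self.names.append("slope_mean")
        if "slope_sd" not in self.fixed:
            self.names.append("log_slope_sd")
        if "met0" not in self.fixed:
            if pop.met_mode == "per_item":
                self.names += [f"log_met0[{it.item_id}]" for it in pop.items]
            else:
                self.names.append("log_met0")
        if pop.met_time_mode != "constant" and "met_tslope" not in self.fixed:
            self.names.append("met_tslope")
        if "met_iiv_sd" not in self.fixed:
            self.names.append("log_met_iiv_sd")

    @property
    def n(self) -> int:
        return len(self.names)

    def pack(self, pop: PopulationParams) -> np.ndarray:
        x = []
        for it in pop.items:
            x.append(np.log(it.a))
            x.append(it.b[0])
            db = np.diff(it.b)
            x.extend(np.log(np.maximum(db, _MIN_B_GAP)))
        x.append(pop.slope_mean)
        if "slope_sd" not in self.fixed:
            x.append(np.log(max(pop.slope_sd, 1e-8)))
        if "met0" not in self.fixed:
            x.extend(np.log(np.atleast_1d(pop.met0)))
        if pop.met_time_mode != "constant" and "met_tslope" not in self.fixed:
            x.append(pop.met_tslope)
        if "met_iiv_sd" not in self.fixed:
            x.append(np.log(max(pop.met_iiv_sd, 1e-8)))
        return np.array(x)

    def unpack(self, x: np.ndarray) -> PopulationParams:
        pos = 0
        items = []
        for it in self.template.items:
            a = float(np.exp(x[pos])); pos += 1
            b1 = float(x[pos]); pos += 1
            K = it.n_categories
            db = np.exp(x[pos : pos + K - 2]); pos += K - 2
            b = b1 + np.concatenate([[0.0], np.cumsum(db)])
            items.append(ItemSpec(it.item_id, K, a, tuple(b)))
        slope_mean = float(x[pos]); pos += 1
        if "slope_sd" in self.fixed:
            slope_sd = float(self.fixed["slope_sd"])
        else:
            slope_sd = float(np.exp(x[pos])); pos += 1
        if "met0" in self.fixed:
            met0 = self.fixed["met0"]
        elif self.template.met_mode == "per_item":
            met0 = tuple(np.exp(x[pos : pos + len(items)])); pos += len(items)
        else:
            met0 = float(np.exp(x[pos])); pos += 1
        if self.template.met_time_mode != "constant" and "met_tslope" not in self.fixed:
            met_tslope = float(x[pos]); pos += 1
        else:
            met_tslope = float(self.fixed.get("met_tslope", self.template.met_tslope))
        if "met_iiv_sd" in self.fixed:
            met_iiv_sd = float(self.fixed["met_iiv_sd"])
        else:
            met_iiv_sd = float(np.exp(x[pos])); pos += 1
        return replace(
            self.template,
            items=tuple(items),
            slope_mean=slope_mean,
            slope_sd=slope_sd,
            met0=met0,
            met_tslope=met_tslope,
            met_iiv_sd=met_iiv_sd,
        )

    def natural_jacobian(self, pop: PopulationParams):
        """Names and Jacobian of natural-scale parameters w.r.t. the
        unconstrained vector (delta method for standard errors)."""
        names: list[str] = []
        rows: list[np.ndarray] = []
        pos = 0
        for it in pop.items:
            K = it.n_categories
            r = np.zeros(self.n)
            r[pos] = it.a                      # d a / d log a
            names.append(f"a[{it.item_id}]")
            rows.append(r)
            incs = np.diff(it.b)
            for k in range(1, K):
                r = np.zeros(self.n)
                r[pos + 1] = 1.0               # b1 shifts every cut-point
                for m in range(k - 1):
                    r[pos + 2 + m] = max(incs[m], _MIN_B_GAP)
                names.append(f"b{k}[{it.item_id}]")
                rows.append(r)
            pos += 1 + (K - 1)
        names.append("slope_mean")
        r = np.zeros(self.n); r[pos] = 1.0; rows.append(r); pos += 1
        if "slope_sd" not in self.fixed:
            names.append("slope_sd")
            r = np.zeros(self.n); r[pos] = pop.slope_sd; rows.append(r); pos += 1
        if "met0" not in self.fixed:
            for m0 in np.atleast_1d(pop.met0):
                names.append("met0" if self.template.met_mode == "shared" else f"met0[{pos}]")
                r = np.zeros(self.n); r[pos] = float(m0); rows.append(r); pos += 1
        if pop.met_time_mode != "constant" and "met_tslope" not in self.fixed:
            names.append("met_tslope")
            r = np.zeros(self.n); r[pos] = 1.0; rows.append(r); pos += 1
        if "met_iiv_sd" not in self.fixed:
            names.append("met_iiv_sd")
            r = np.zeros(self.n); r[pos] = pop.met_iiv_sd; rows.append(r); pos += 1
        return names, np.array(rows)

    def grad_to_x(self, pop: PopulationParams, g: dict, x: np.ndarray) -> np.ndarray:
        """Chain natural-parameter gradients onto the unconstrained scale."""
        gx = np.zeros(self.n)
        pos = 0
        for i, it in enumerate(pop.items):
            K = it.n_categories
            gx[pos] = g["da"][i] * it.a; pos += 1
            db_grad = g["db"][i, : K - 1]           # d ll / d b_k
            gx[pos] = db_grad.sum(); pos += 1       # b1 shifts every cut-point
            for k in range(K - 2):
                inc = it.b[k + 1] - it.b[k]
                gx[pos] = db_grad[k + 1 :].sum() * max(inc, _MIN_B_GAP); pos += 1
        gx[pos] = g["dslope_mean"]; pos += 1
        if "slope_sd" not in self.fixed:
            gx[pos] = g["dslope_sd"] * pop.slope_sd; pos += 1
        if "met0" not in self.fixed:
            met0 = np.atleast_1d(pop.met0)
            dmet0 = np.atleast_1d(g["dmet0"])
            for m0, dm in zip(met0, dmet0):
                gx[pos] = dm * m0; pos += 1
        if pop.met_time_mode != "constant" and "met_tslope" not in self.fixed:
            gx[pos] = g["dmet_tslope"]; pos += 1
        if "met_iiv_sd" not in self.fixed:
            gx[pos] = g["dmet_iiv"] * pop.met_iiv_sd; pos += 1
        return gx


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of a marginal maximum-likelihood fit.

    ``ofv`` is -2 log marginal likelihood (lower is better); ``ebes`` holds
    the per-subject empirical Bayes effect estimates (inner Laplace modes, in
    natural units).
    """

    estimates: PopulationParams
    ofv: float
    converged: bool
    n_iter: int
    message: str
    ebes: pd.DataFrame
    se: dict | None = None
    fixed: dict = field(default_factory=dict)

    @property
    def loglik(self) -> float:
        return -0.5 * self.ofv


def fit(
    dataset: DiaryDataset,
    init: PopulationParams | None = None,
    fixed: dict | None = None,
    max_iter: int = 150,
    gtol: float = 1.0,
    ftol: float = 1e-6,
    refine: int = 0,
    compute_se: bool = False,
    verbose: bool = False,
) -> FitResult:
    """Maximise the Laplace marginal likelihood over the population
    parameters.

    ``fixed`` pins parameters by name, e.g. ``{"met0": 0.1, "met_iiv_sd": 0}``
    for the no-Markov reference model (MET fixed to a small value).  Item
    difficulty ordering is enforced by the increment parameterisation.
    ``refine`` adds that many Newton steps with fully finite-differenced
    objective gradients after the quasi-Newton phase (exact but expensive:
    ~2 x n_params objective evaluations per step; useful on small problems
    when the optimum must be resolved below ~0.5 OFV units).
    Non-convergence returns the best-found values with ``converged=False``.
    """
    if init is None:
        init = init_from_collapsed_fits(dataset)
    fixed = dict(fixed or {})
    if fixed.get("met_iiv_sd") == 0 or fixed.get("met0") is not None:
        fixed.setdefault("met_iiv_sd", 0.0)
        init = replace(init, met_iiv_sd=float(fixed["met_iiv_sd"]))
    if "met0" in fixed:
        init = replace(init, met0=fixed["met0"])
    if "slope_sd" in fixed:
        init = replace(init, slope_sd=float(fixed["slope_sd"]))

    packed = _pack(dataset)
    tmap = _ThetaMap(init, fixed)
    state = _LaplaceState(packed.n_subj, len(_active_dims(init)))
    x0 = tmap.pack(init)
    n_eval = [0]
    t0 = time.time()

    def theta_grad_at(pop, x, dims, eta, core=None):
        """Gradient of the conditional loglik w.r.t. the unconstrained
        parameter vector, holding the standardized effects fixed."""
        if core is None:
            eff = _eta_to_eff(pop, eta, dims)
            core = _core_loglik(packed, pop, eff, packed.subj, need_grad=True)
            if core is None:
                return None
        g_eff = core["grad_eff"]
        gi = _theta_item_grads(packed, pop, core)
        g = {
            "da": gi["da"],
            "db": gi["db"],
            "dmet0": gi["dmet0"],
            "dmet_tslope": gi["dmet_tslope"],
            "dslope_mean": g_eff[:, 1].sum(),
            "dslope_sd": 0.0,
            "dmet_iiv": 0.0,
        }
        if 1 in dims:
            g["dslope_sd"] = float((eta[:, dims.index(1)] * g_eff[:, 1]).sum())
        if 2 in dims:
            g["dmet_iiv"] = float((eta[:, dims.index(2)] * g_eff[:, 2]).sum())
        return tmap.grad_to_x(pop, g, x)

    def objective(x):
        n_eval[0] += 1
        pop = tmap.unpack(x)
        sol = _laplace_loglik(packed, pop, state)
        if sol is None or not np.all(np.isfinite(sol["per_subject"])):
            return 1e12, np.zeros_like(x)
        ll = sol["per_subject"].sum()
        dims = sol["dims"]
        na = len(dims)
        eta = sol["eta"]
        gx = theta_grad_at(pop, x, dims, eta, core=sol["core"])
        # explicit parameter-dependence of the log-determinant term:
        # d logdet H / d theta = tr(H^-1 dH/dtheta)
        #   = -sum_k (1/w_k) d^2/de^2 [d loglik/d theta](eta + e V_k),
        # evaluated per subject along the eigenvectors of the inner Hessian
        if na:
            wH, VH = sol["H_eigs"]
            eps = 0.05
            gx_center = gx
            correction = np.zeros_like(gx)
            for k in range(na):
                # the 1/w_k trace weight is folded into the per-subject
                # perturbation size: (u/sqrt(w))' Hess (u/sqrt(w)) = (1/w) u'Hu
                u = VH[:, :, k] / np.sqrt(wH[:, k])[:, None]
                gp = theta_grad_at(pop, x, dims, eta + eps * u)
                gm = theta_grad_at(pop, x, dims, eta - eps * u)
                if gp is None or gm is None:
                    continue
                correction += 0.5 * (gp + gm - 2.0 * gx_center) / eps**2
            gx = gx_center + correction
        if verbose:
            print(f"  eval {n_eval[0]:4d}  OFV {-2 * ll:.3f}  t {time.time() - t0:.0f}s")
        return -2.0 * ll, -2.0 * gx

    # restarts clear the quasi-Newton memory; the line search can stall on
    # the slightly inconsistent (approximate) gradient, and a fresh start
    # from the stall point recovers the remaining progress
    res = None
    x_cur = x0
    for _restart in range(6):
        r = optimize.minimize(
            objective,
            x_cur,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": ftol, "gtol": gtol, "maxcor": 20},
        )
        improved = res is None or r.fun < res.fun - 0.05
        if res is None or r.fun < res.fun:
            res = r
        x_cur = r.x
        if not improved or r.fun >= 1e11:
            break

    if refine > 0 and res.fun < 1e11:
        x_cur, f_cur = res.x.copy(), res.fun
        Hr = _fd_hessian(objective, x_cur)
        wr, Vr = np.linalg.eigh(Hr)
        wr = np.maximum(wr, 1e-2)
        fd = 5e-4
        eta_snap = state.eta.copy()
        for _ in range(refine):
            # restore the warm-start cache before each evaluation so the FD
            # differences are free of path-dependent inner-mode noise
            g_full = np.empty_like(x_cur)
            for j in range(len(x_cur)):
                xp, xm = x_cur.copy(), x_cur.copy()
                xp[j] += fd
                xm[j] -= fd
                state.eta = eta_snap.copy()
                fp = objective(xp)[0]
                state.eta = eta_snap.copy()
                fm = objective(xm)[0]
                g_full[j] = (fp - fm) / (2 * fd)
            step = -Vr @ ((Vr.T @ g_full) / wr)
            state.eta = eta_snap.copy()
            f_new = objective(x_cur + step)[0]
            for _bt in range(10):
                if f_new <= f_cur:
                    break
                step *= 0.5
                state.eta = eta_snap.copy()
                f_new = objective(x_cur + step)[0]
            if f_new > f_cur - 1e-9:
                break
            x_cur, f_cur = x_cur + step, f_new
            objective(x_cur)
            eta_snap = state.eta.copy()
        res.x, res.fun = x_cur, f_cur

    pop_hat = tmap.unpack(res.x)
    sol = _laplace_loglik(packed, pop_hat, state)
    dims = sol["dims"]
    eff_hat = _eta_to_eff(pop_hat, sol["eta"], dims)
    ebes = pd.DataFrame(
        {
            "subject_id": packed.subject_ids,
            "d0": eff_hat[:, 0],
            "slope": eff_hat[:, 1],
            "eta_met": eff_hat[:, 2],
        }
    )
    se = None
    if compute_se:
        se = _standard_errors(_fd_hessian(objective, res.x), tmap, pop_hat)
    converged = bool(res.success) or res.status == 0
    return FitResult(
        estimates=pop_hat,
        ofv=float(sol["per_subject"].sum() * -2.0),
        converged=converged,
        n_iter=int(res.nit),
        message=str(res.message),
        ebes=ebes,
        se=se,
        fixed=fixed,
    )


def _fd_hessian(objective, x_hat: np.ndarray, step: float = 1e-3) -> np.ndarray:
    """Finite-difference Hessian of the OFV from its gradient."""
    n = len(x_hat)
    g0 = objective(x_hat)[1]
    H = np.empty((n, n))
    for j in range(n):
        xp = x_hat.copy()
        xp[j] += step
        H[:, j] = (objective(xp)[1] - g0) / step
    return 0.5 * (H + H.T)


def _standard_errors(H: np.ndarray, tmap: _ThetaMap, pop: PopulationParams):
    """Asymptotic SEs from the OFV Hessian (information = Hessian/2), on the
    unconstrained scale and, via the delta method, on the natural scale.

    The finite-difference Hessian can be indefinite along near-flat
    directions; eigenvalues are floored at a small positive fraction of the
    largest one, which maps non-identified directions to large (not zero or
    imaginary) standard errors.
    """
    w, V = np.linalg.eigh(0.5 * H)
    floor = 1e-6 * max(float(w.max()), 1e-12)
    w = np.maximum(np.abs(w), floor)   # modified-Cholesky-style regularisation
    cov = (V / w) @ V.T
    var = np.clip(np.diag(cov), 0.0, None)
    se = {name: float(np.sqrt(v)) for name, v in zip(tmap.names, var)}
    names_nat, J = tmap.natural_jacobian(pop)
    var_nat = np.clip(np.einsum("ij,jk,ik->i", J, cov, J), 0.0, None)
    se["natural"] = {n: float(np.sqrt(v)) for n, v in zip(names_nat, var_nat)}
    return se


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


def compare_models(ofv_full: float, ofv_reduced: float, df: int) -> dict:
    """Likelihood-ratio comparison of nested models on the OFV scale.

    ``delta_ofv = ofv_reduced - ofv_full`` is chi-square distributed with
    ``df`` degrees of freedom under the reduced model; a drop larger than
    3.84 corresponds to p < 0.05 for one degree of freedom.
    """
    if df < 0:
        raise ValueError("degrees of freedom must be >= 0")
    delta = float(ofv_reduced - ofv_full)
    p = float(stats.chi2.sf(max(delta, 0.0), df)) if df > 0 else float("nan")
    return {
        "delta_ofv": delta,
        "df": df,
        "p_value": p,
        "preferred": "full" if delta > stats.chi2.ppf(0.95, max(df, 1)) else "reduced",
    }


# ---------------------------------------------------------------------------
# collapsed-category initialisation
# ---------------------------------------------------------------------------

_SCHEMES_5 = {
    "a": (np.array([0, 1, 2, 2, 2]), (1, 2)),  # cut-points -> b1, b2
    "b": (np.array([0, 0, 1, 2, 2]), (2, 3)),  # -> b2, b3
    "c": (np.array([0, 0, 0, 1, 2]), (3, 4)),  # -> b3, b4
}
_SCHEMES_4 = {
    "a": (np.array([0, 1, 2, 2]), (1, 2)),
    "b": (np.array([0, 0, 1, 2]), (2, 3)),
}


def _collapsed_item_fit(
    n_subj, f_subj, f_score, t_subj, tprev, tcur, tdt, tn, met_init=1.0, n_nodes=8
):
    """Mixed-model ML fit of one collapsed 3-category item.

    Baseline severity is integrated over its fixed N(0,1) population law by
    Gauss-Hermite quadrature (discrimination is only identified through the
    between-subject heterogeneity); transitions use the analytic 3-state
    kernel.  ``f_*`` index the first observations, ``t_*`` the aggregated
    transition counts per (subject, prev, cur, dt).  Returns (a, b1, b2, met).
    """
    x_gh, w_gh = roots_hermite(n_nodes)
    d_nodes = np.sqrt(2.0) * x_gh                    # N(0,1) quadrature points
    logw = np.log(w_gh / np.sqrt(np.pi))
    dts, dt_idx = np.unique(tdt, return_inverse=True)
    n_dt = len(dts)

    def nll(x):
        a = np.exp(x[0])
        b = np.array([x[1], x[1] + np.exp(x[2])])
        met = np.exp(x[3])
        c = expit(a * (d_nodes[:, None] - b[None, :]))        # (Q, 2)
        pi = np.stack([1.0 - c[:, 0], c[:, 0] - c[:, 1], c[:, 1]], axis=1)
        pi = np.maximum(pi, PROB_FLOOR)
        logpi = np.log(pi / pi.sum(axis=1, keepdims=True))
        ll = np.zeros((n_nodes, n_subj))
        np.add.at(ll, (slice(None), f_subj), logpi[:, f_score])
        if n_dt:
            pi_rep = np.repeat(pi, n_dt, axis=0)
            met_rep = np.full(n_nodes * n_dt, met)
            dt_rep = np.tile(dts, n_nodes)
            P = _spectral.kernel3_closed_form(pi_rep, met_rep, dt_rep)
            lp = np.log(np.maximum(P, 1e-300)).reshape(n_nodes, n_dt, 3, 3)
            contrib = tn[None, :] * lp[:, dt_idx, tprev, tcur]   # (Q, n_keys)
            np.add.at(ll, (slice(None), t_subj), contrib)
        ll += logw[:, None]
        mx = ll.max(axis=0)
        return -float(np.sum(mx + np.log(np.exp(ll - mx[None, :]).sum(axis=0))))

    x0 = np.array([0.3, -1.0, 0.5, np.log(met_init)])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 600, "xatol": 1e-4, "fatol": 1e-6})
    a = float(np.exp(res.x[0]))
    b1 = float(res.x[1])
    b2 = float(res.x[1] + np.exp(res.x[2]))
    met = float(np.exp(res.x[3]))
    return a, b1, b2, met


def init_from_collapsed_fits(dataset: DiaryDataset) -> PopulationParams:
    """Initial population parameters from per-item 3-category collapsed fits.

    Each item's scores are merged into 3 categories in up to three overlapping
    ways (0|1|rest, low|mid|high, rest|next-to-top|top), each collapsed
    dataset is fitted with the closed-form 3-state model, and the cut-point
    estimates are mapped back onto the item's difficulty vector (averaging
    where two schemes estimate the same cut-point).  The initial MET is the
    mean of the collapsed-fit METs.  Trajectory and IIV parameters get
    neutral starting values.
    """
    packed = _pack(dataset)
    items_out = []
    met_all = []
    for i, it in enumerate(dataset.items):
        sel = packed.item == i
        schemes = _SCHEMES_5 if it.n_categories == 5 else _SCHEMES_4
        b_acc: dict[int, list[float]] = {}
        a_acc = []
        for _name, (mapping, cuts) in schemes.items():
            score_c = mapping[packed.score[sel]]
            first = packed.is_first[sel]
            prev_c = np.where(first, -1, mapping[np.maximum(packed.prev[sel], 0)])
            subj = packed.subj[sel]
            dts = packed.dt[sel]
            key = np.stack(
                [subj[~first], prev_c[~first], score_c[~first], dts[~first]], axis=1
            )
            uniq, tn = np.unique(key, axis=0, return_counts=True)
            a_hat, b1_hat, b2_hat, met_hat = _collapsed_item_fit(
                packed.n_subj,
                subj[first],
                score_c[first],
                uniq[:, 0].astype(int),
                uniq[:, 1].astype(int),
                uniq[:, 2].astype(int),
                uniq[:, 3],
                tn.astype(float),
            )
            a_acc.append(a_hat)
            met_all.append(met_hat)
            for cut, val in zip(cuts, (b1_hat, b2_hat)):
                b_acc.setdefault(cut, []).append(val)
        a0 = float(np.clip(np.mean(a_acc), 0.2, 6.0))
        b = []
        for k in range(1, it.n_categories):
            vals = [v for v in b_acc.get(k, []) if np.isfinite(v) and abs(v) < 8]
            if vals:
                b.append(float(np.mean(vals)))
            else:  # unobserved extreme category: seed from the neighbour
                b.append((b[-1] + 0.5) if b else 0.0)
        b = np.array(b)
        for k in range(1, len(b)):  # enforce ordering with a minimal gap
            b[k] = max(b[k], b[k - 1] + 0.05)
        items_out.append(ItemSpec(it.item_id, it.n_categories, a0, tuple(b)))
    met0 = float(np.clip(np.mean(met_all), 0.05, 50.0))
    return PopulationParams(
        items=tuple(items_out),
        slope_mean=0.0,
        slope_sd=0.05,
        met0=met0,
        met_tslope=0.0,
        met_iiv_sd=0.2,
        met_mode="shared",
        met_time_mode="constant",
    )
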