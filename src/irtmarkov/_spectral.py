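"""Batched spectral computation of birth-death transition kernels.

The item-level generator Q is reversible with respect to its stationary law
``pi`` (detailed balance holds by construction), so
``M = diag(sqrt(pi)) @ Q @ diag(1/sqrt(pi))`` is symmetric and

    P(dt) = expm(Q dt) = diag(1/sqrt(pi)) @ V exp(w dt) V.T @ diag(sqrt(pi))

with ``M = V diag(w) V.T`` the (batched) symmetric eigendecomposition.  All
routines here operate on stacks of intervals at once; they are the hot path of
the marginal likelihood and of trajectory simulation.

Gradients use the standard eigendecomposition form of the Frechet derivative
of the matrix exponential: for symmetric ``M``,
``d expm(M t) = V (Phi o (V.T dM V)) V.T`` where
``Phi_ij = (e^{w_i t} - e^{w_j t}) / (w_i - w_j)`` (divided differences,
``t e^{w_i t}`` on the diagonal).  A useful exact shortcut: every entry of M
scales as 1/MET, so the derivative of the kernel with respect to log MET is
``-dt * M @ P`` and needs no extra decomposition.
"""

from __future__ import annotations

import numpy as np

_TINY = 1e-300


def build_symmetric_generator(pi: np.ndarray, met: np.ndarray):
    """Symmetrised generator stack M (n, K, K) plus pair quantities.

    Parameters
    ----------
    pi : (n, K) stationary probabilities (already floored, each row sums ~1).
    met : (n,) individual MET values in days.

    Returns
    -------
    M : (n, K, K) symmetric tridiagonal stack.
    aux : dict with per-pair arrays used by the gradient chain
        (u, v, s, m  -- all shaped (n, K-1)).
    """
    pi = np.asarray(pi, dtype=float)
    met = np.asarray(met, dtype=float)[:, None]
    n, K = pi.shape
    u = pi[:, :-1]
    v = pi[:, 1:]
    s = u + v
    inv = 1.0 / (met * s)
    lam_up = v * inv
    lam_down = u * inv
    m = np.sqrt(u * v) * inv
    M = np.zeros((n, K, K))
    idx = np.arange(K - 1)
    M[:, idx, idx + 1] = m
    M[:, idx + 1, idx] = m
    diag = np.zeros((n, K))
    diag[:, :-1] -= lam_up
    diag[:, 1:] -= lam_down
    M[:, np.arange(K), np.arange(K)] = diag
    return M, {"u": u, "v": v, "s": s, "m": m, "met": met[:, 0]}


def full_kernels(pi: np.ndarray, met: np.ndarray, dt: np.ndarray) -> np.ndarray:
    """Stack of full K x K transition kernels expm(Q dt) (rows renormalised)."""
    M, _ = build_symmetric_generator(pi, met)
    w, V = np.linalg.eigh(M)
    ew = np.exp(w * np.asarray(dt, dtype=float)[:, None])
    E = np.einsum("nik,nk,njk->nij", V, ew, V)
    sp = np.sqrt(np.asarray(pi, dtype=float))
    P = E * (sp[:, None, :] / sp[:, :, None])
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P


def _phi_matrix(w: np.ndarray, dt: np.ndarray) -> np.ndarray:
    """Divided-difference matrix Phi_ij for the expm Frechet derivative."""
    wd = w * dt[:, None]                     # (n, K)
    wi = wd[:, :, None]
    wj = wd[:, None, :]
    diff = wi - wj
    small = np.abs(diff) < 1e-7
    # generic branch: (e^wi - e^wj) / (wi - wj) * dt
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (np.exp(wi) - np.exp(wj)) / np.where(small, 1.0, diff)
    mid = np.exp(0.5 * (wi + wj)) * (1.0 + diff * diff / 24.0)
    phi = np.where(small, mid, phi)
    return phi * dt[:, None, None]


def kernel_entry_terms(
    pi: np.ndarray,
    met: np.ndarray,
    dt: np.ndarray,
    prev: np.ndarray,
    cur: np.ndarray,
    need_grad: bool = False,
):
    """Log kernel entries log P[prev, cur](dt) and, optionally, gradients.

    Returns a dict with

    ``logp``          (n,) log transition probabilities;
    ``dlogp_dpi``     (n, K) gradient w.r.t. the (floored) stationary
                      probabilities (only with ``need_grad``);
    ``dlogp_dlogmet`` (n,) gradient w.r.t. log MET (only with ``need_grad``).
    """
    pi = np.asarray(pi, dtype=float)
    met = np.asarray(met, dtype=float)
    dt = np.asarray(dt, dtype=float)
    prev = np.asarray(prev)
    cur = np.asarray(cur)
    n, K = pi.shape
    rows = np.arange(n)

    M, aux = build_symmetric_generator(pi, met)
    w, V = np.linalg.eigh(M)
    ew = np.exp(w * dt[:, None])
    Vr = V[rows, prev, :]
    Vc = V[rows, cur, :]
    E = np.sum(Vr * Vc * ew, axis=1)
    pi_r = pi[rows, prev]
    pi_c = pi[rows, cur]
    with np.errstate(divide="ignore"):
        # numerically non-positive entries report log P = -inf (never raised)
        logp = 0.5 * (np.log(pi_c) - np.log(pi_r)) + np.log(np.clip(E, 0.0, None))
    out = {"logp": logp}
    if not need_grad:
        return out

    ok = E > _TINY
    Einv = np.where(ok, 1.0 / np.maximum(E, _TINY), 0.0)

    # d log P / d log MET = -dt * (M E)_rc / E_rc, via the 1/MET scaling of M
    ME = np.sum(Vr * Vc * w * ew, axis=1)
    out["dlogp_dlogmet"] = np.where(ok, -dt * ME * Einv, 0.0)

    # gradient w.r.t. M through the Frechet derivative, then chain to pi
    phi = _phi_matrix(w, dt)
    S = 0.5 * (Vr[:, :, None] * Vc[:, None, :] + Vc[:, :, None] * Vr[:, None, :])
    A = phi * S
    G = np.matmul(V, np.matmul(A, V.transpose(0, 2, 1)))  # dE_rc/dM, symmetric

    u, v, s, m = aux["u"], aux["v"], aux["s"], aux["m"]
    metc = aux["met"][:, None]
    idx = np.arange(K - 1)
    goff = G[:, idx, idx + 1]
    gdiag = G[:, np.arange(K), np.arange(K)]
    gd_lo = gdiag[:, :-1]   # G[k, k]
    gd_hi = gdiag[:, 1:]    # G[k+1, k+1]
    inv_ms2 = 1.0 / (metc * s * s)
    # per adjacent pair k: d E / d pi_k and d E / d pi_{k+1}
    dE_du = goff * m * (v - u) / (u * s) + (gd_lo - gd_hi) * v * inv_ms2
    dE_dv = goff * m * (u - v) / (v * s) + (gd_hi - gd_lo) * u * inv_ms2
    dpi = np.zeros((n, K))
    dpi[:, :-1] += dE_du
    dpi[:, 1:] += dE_dv
    dpi *= Einv[:, None]
    # stationary-ratio prefactor sqrt(pi_c / pi_r)
    dpi[rows, cur] += 0.5 / pi_c
    dpi[rows, prev] -= 0.5 / pi_r
    out["dlogp_dpi"] = np.where(ok[:, None], dpi, 0.0)
    return out


def kernel3_closed_form(pi: np.ndarray, met: np.ndarray, dt: np.ndarray) -> np.ndarray:
    """Closed-form 3-state kernels (analytic eigenvalues, no iterative expm).

    For K = 3 the symmetrised generator has eigenvalues 0, mu1, mu2 with
    ``mu1 + mu2 = tr(M)`` and ``mu1 * mu2`` the sum of principal 2x2 minors;
    the kernel follows from the spectral projectors.  Used by the collapsed
    3-category initialisation fits.
    """
    pi = np.asarray(pi, dtype=float)
    met = np.asarray(met, dtype=float)
    dt = np.asarray(dt, dtype=float)
    M, _ = build_symmetric_generator(pi, met)
    tr = np.trace(M, axis1=1, axis2=2)
    # sum of principal 2x2 minors (M[0,2] = 0 for tridiagonal 3x3)
    e2 = (
        M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] ** 2
        + M[:, 0, 0] * M[:, 2, 2]
        + M[:, 1, 1] * M[:, 2, 2] - M[:, 1, 2] ** 2
    )
    disc = np.sqrt(np.maximum(tr * tr - 4.0 * e2, 0.0))
    mu1 = 0.5 * (tr + disc)
    mu2 = 0.5 * (tr - disc)
    sp = np.sqrt(pi)
    P0 = sp[:, :, None] * sp[:, None, :] / np.sum(pi, axis=1)[:, None, None]
    eye = np.eye(3)[None]
    sep = np.abs(mu1 - mu2) > 1e-12 * np.maximum(np.abs(mu1), 1.0)
    d1 = np.where(sep, mu1 * (mu1 - mu2), 1.0)
    d2 = np.where(sep, mu2 * (mu2 - mu1), 1.0)
    P1 = np.matmul(M, M - mu2[:, None, None] * eye) / d1[:, None, None]
    P2 = np.matmul(M, M - mu1[:, None, None] * eye) / d2[:, None, None]
    E = (
        P0
        + np.exp(mu1 * dt)[:, None, None] * P1
        + np.exp(mu2 * dt)[:, None, None] * P2
    )
    if not np.all(sep):  # (near-)degenerate pair: fall back to eigh rows
        bad = ~sep
        w, V = np.linalg.eigh(M[bad])
        ew = np.exp(w * dt[bad][:, None])
        E[bad] = np.einsum("nik,nk,njk->nij", V, ew, V)
    P = E * (sp[:, None, :] / sp[:, :, None])
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P
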