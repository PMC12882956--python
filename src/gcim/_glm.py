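"""Batched per-SNP regression engine.

Genome-wide scans fit the same small regression once per SNP (design =
shared covariate block + one or two SNP-specific columns).  Looping over a
general-purpose fitter is prohibitively slow at simulation scale, so the
normal equations (linear) and Newton-Raphson iterations (logistic) are
vectorized across SNPs, chunked to bound memory.  Correctness is pinned to
statsmodels / explicit normal-equation oracles in the test suite.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy import special, stats

FLAG_OK = "ok"
FLAG_MONOMORPHIC = "monomorphic"
FLAG_NONCONVERGED = "nonconverged"
FLAG_SINGULAR = "singular"

_MAX_ABS_BETA = 1e3  # logistic |coefficient| beyond this is treated as separation
_STEP_CAP = 4.0      # max-norm cap on a Newton step (damping near separation)


def _build_designs(Z: np.ndarray, Gc: np.ndarray, scalers: Sequence[np.ndarray]) -> np.ndarray:
    """Stack per-SNP design matrices: D[j] = [Z, g_j*s_1, ..., g_j*s_q]."""
    n, k = Z.shape
    mc = Gc.shape[1]
    q = len(scalers)
    D = np.empty((mc, n, k + q))
    D[:, :, :k] = Z[None, :, :]
    for i, s in enumerate(scalers):
        D[:, :, k + i] = (Gc * s[:, None]).T
    return D


def batched_linear(
    y: np.ndarray,
    Z: np.ndarray,
    G: np.ndarray,
    scalers: Sequence[np.ndarray],
    chunk: int = 256,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """OLS of y on [Z, g_j*s_1, ...] for every SNP column g_j of G.

    Returns (beta, se, pval, flags), each with one row per SNP; p-values are
    two-sided t-tests with n - p degrees of freedom.
    """
    n, m = G.shape
    k = Z.shape[1]
    p = k + len(scalers)
    beta = np.full((m, p), np.nan)
    se = np.full((m, p), np.nan)
    pval = np.full((m, p), np.nan)
    flags = np.full(m, FLAG_OK, dtype=object)

    mono = G.std(axis=0) == 0
    flags[mono] = FLAG_MONOMORPHIC
    todo = np.flatnonzero(~mono)
    df = n - p

    for start in range(0, len(todo), chunk):
        idx = todo[start : start + chunk]
        D = _build_designs(Z, G[:, idx], scalers)
        XtX = np.einsum("jnp,jnq->jpq", D, D, optimize=True)
        Xty = np.einsum("jnp,n->jp", D, y, optimize=True)
        try:
            b = np.linalg.solve(XtX, Xty[..., None])[..., 0]
        except np.linalg.LinAlgError:
            b = np.full((len(idx), p), np.nan)
            for jj in range(len(idx)):
                try:
                    b[jj] = np.linalg.solve(XtX[jj], Xty[jj])
                except np.linalg.LinAlgError:
                    flags[idx[jj]] = FLAG_SINGULAR
        fitted = np.einsum("jnp,jp->jn", D, b, optimize=True)
        rss = ((y[None, :] - fitted) ** 2).sum(axis=1)
        sigma2 = rss / df
        try:
            xtx_inv = np.linalg.inv(XtX)
            var = sigma2[:, None] * np.einsum("jpp->jp", xtx_inv)
        except np.linalg.LinAlgError:
            var = np.full((len(idx), p), np.nan)
            for jj in range(len(idx)):
                try:
                    var[jj] = sigma2[jj] * np.diag(np.linalg.inv(XtX[jj]))
                except np.linalg.LinAlgError:
                    pass
        s = np.sqrt(np.clip(var, 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = b / s
        beta[idx] = b
        se[idx] = s
        pval[idx] = 2.0 * stats.t.sf(np.abs(t), df)

    bad = np.isin(flags, (FLAG_MONOMORPHIC, FLAG_SINGULAR))
    beta[bad] = np.nan
    se[bad] = np.nan
    pval[bad] = np.nan
    return beta, se, pval, flags


def _null_logistic(y: np.ndarray, Z: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Plain Newton fit of the covariate-only logistic model (warm start)."""
    b = np.zeros(Z.shape[1])
    # start intercept at logit of the base rate when an intercept column exists
    const = np.flatnonzero((Z == 1).all(axis=0))
    if const.size:
        pbar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
        b[const[0]] = np.log(pbar / (1 - pbar))
    for _ in range(max_iter):
        eta = Z @ b
        mu = special.expit(eta)
        w = mu * (1 - mu) + 1e-12
        grad = Z.T @ (y - mu)
        H = (Z * w[:, None]).T @ Z
        step = np.linalg.solve(H, grad)
        b = b + step
        if np.abs(step).max() < 1e-10:
            break
    return b


def _loglik(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    # log L = sum y*eta - log(1 + exp(eta)), stable for large |eta|
    return (y[None, :] * eta - np.logaddexp(0.0, eta)).sum(axis=1)


def batched_logistic(
    y: np.ndarray,
    Z: np.ndarray,
    G: np.ndarray,
    scalers: Sequence[np.ndarray],
    chunk: int = 256,
    max_iter: int = 40,
    tol: float = 1e-6,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Logistic regression of y on [Z, g_j*s_1, ...] for every SNP.

    Damped Newton-Raphson (per-SNP step cap), warm-started from the shared
    covariate-only fit.  Returns (beta, se, pval, flags); p-values are Wald
    z-tests.  SNPs showing separation or failing to converge are flagged.
    """
    n, m = G.shape
    k = Z.shape[1]
    p = k + len(scalers)
    beta = np.full((m, p), np.nan)
    se = np.full((m, p), np.nan)
    pval = np.full((m, p), np.nan)
    flags = np.full(m, FLAG_OK, dtype=object)

    mono = G.std(axis=0) == 0
    flags[mono] = FLAG_MONOMORPHIC
    todo = np.flatnonzero(~mono)
    b_null = _null_logistic(y, Z)

    for start in range(0, len(todo), chunk):
        idx = todo[start : start + chunk]
        mc = len(idx)
        D = _build_designs(Z, G[:, idx], scalers)
        b = np.zeros((mc, p))
        b[:, :k] = b_null[None, :]
        eta = np.einsum("jnp,jp->jn", D, b, optimize=True)
        converged = np.zeros(mc, dtype=bool)

        # Active-set damped Newton: each SNP's step is capped in max-norm
        # (trust-region style) so near-separated fits cannot overshoot, and
        # converged or diverging SNPs are frozen so a handful of pathological
        # fits cannot force full-cost iterations on the whole chunk.
        active = np.arange(mc)
        for _ in range(max_iter):
            Da = D[active]
            mu = special.expit(eta[active])
            w = mu * (1 - mu) + 1e-12
            grad = np.einsum("jnp,jn->jp", Da, y[None, :] - mu, optimize=True)
            H = np.einsum("jnp,jn,jnq->jpq", Da, w, Da, optimize=True)
            try:
                step = np.linalg.solve(H, grad[..., None])[..., 0]
            except np.linalg.LinAlgError:
                step = np.zeros((len(active), p))
                for jj in range(len(active)):
                    try:
                        step[jj] = np.linalg.solve(H[jj], grad[jj])
                    except np.linalg.LinAlgError:
                        flags[idx[active[jj]]] = FLAG_SINGULAR
            norm = np.abs(step).max(axis=1)
            big = norm > _STEP_CAP
            if big.any():
                step[big] *= (_STEP_CAP / norm[big])[:, None]
            cand = b[active] + step
            b[active] = cand
            eta[active] = np.einsum("jnp,jp->jn", Da, cand, optimize=True)
            done = norm < tol
            diverged = np.abs(cand).max(axis=1) > _MAX_ABS_BETA
            converged[active[done]] = True
            active = active[~(done | diverged)]
            if active.size == 0:
                break

        # final information matrix for standard errors
        mu = special.expit(eta)
        w = mu * (1 - mu) + 1e-12
        H = np.einsum("jnp,jn,jnq->jpq", D, w, D, optimize=True)
        var = np.full((mc, p), np.nan)
        try:
            Hinv = np.linalg.inv(H)
            var = np.einsum("jpp->jp", Hinv)
        except np.linalg.LinAlgError:
            for jj in range(mc):
                try:
                    var[jj] = np.diag(np.linalg.inv(H[jj]))
                except np.linalg.LinAlgError:
                    pass
        s = np.sqrt(np.clip(var, 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = b / s
        pv = 2.0 * stats.norm.sf(np.abs(z))

        separated = np.abs(b).max(axis=1) > _MAX_ABS_BETA
        bad_local = separated | ~converged
        for jj in np.flatnonzero(bad_local):
            if flags[idx[jj]] == FLAG_OK:
                flags[idx[jj]] = FLAG_NONCONVERGED
        beta[idx] = b
        se[idx] = s
        pval[idx] = pv

    bad = flags != FLAG_OK
    beta[bad] = np.nan
    se[bad] = np.nan
    pval[bad] = np.nan
    return beta, se, pval, flags
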