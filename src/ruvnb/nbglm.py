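"""Ridge-penalized negative-binomial GLM fitting by IRLS.

Counts y are modelled as NB(mu, phi) with Var(y) = mu + phi mu^2 and
log mu = offset + X b. Coefficients maximize the ridge-penalized
log-likelihood; the dispersion phi, when estimated, maximizes the profile
likelihood on [1e-8, 1e8]. Everything is vectorized over a batch of
responses sharing one design matrix, which is what the factor model's
taxon step, the per-sample update step and differential-abundance testing
all need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, xlogy

PHI_MIN = 1e-8
PHI_MAX = 1e8
ETA_MAX = 30.0
ZERO_FLOOR_LOG = np.log(1e-8)  # intercept floor for all-zero responses


@dataclass
class NbFit:
    """Result of a single NB GLM fit."""

    coef: np.ndarray
    phi: float
    loglik: float
    converged: bool
    n_iter: int


@dataclass
class NbBatchFit:
    """Result of a batch of NB GLM fits sharing a design matrix."""

    coef: np.ndarray  # (B, p)
    phi: np.ndarray  # (B,)
    loglik: np.ndarray  # (B,) unpenalized log-likelihood at the fit
    converged: np.ndarray  # (B,) bool
    all_zero: np.ndarray  # (B,) bool — response had no nonzero count


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Elementwise NB log-pmf with mean/dispersion parameterization."""
    r = 1.0 / np.asarray(phi, dtype=float)
    mu = np.asarray(mu, dtype=float)
    y = np.asarray(y, dtype=float)
    # r*log(r/(r+mu)) written via log1p for stability at tiny phi
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        - r * np.log1p(mu / r)
        + xlogy(y, mu)
        - y * np.log(r + mu)
    )


def _as_batch(Y, offset, n):
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    B = Y.shape[0]
    off = np.asarray(offset, dtype=float) if offset is not None else np.zeros(n)
    off = np.broadcast_to(off, (B, n)) if off.ndim <= 1 else off
    return Y, off


def _penalized_ll(Y, eta, phi_bn, ridge, coef):
    mu = np.exp(np.clip(eta, -ETA_MAX, ETA_MAX))
    ll = nb_loglik(Y, mu, phi_bn).sum(axis=1)
    return ll - 0.5 * (ridge[None, :] * coef**2).sum(axis=1), mu


def _profile_phi_golden(Y, mu, lo=PHI_MIN, hi=PHI_MAX, iters=60, X=None, ridge=None):
    """Per-row maximizer of the NB (adjusted) profile likelihood over phi
    (golden section on log phi; unimodal in practice, boundary-safe).

    With a design ``X`` given, the Cox-Reid adjustment
    -0.5 logdet(X' W X + ridge) is added, removing the downward bias that
    estimating the coefficients induces in the dispersion."""
    a = np.full(Y.shape[0], np.log(lo))
    b = np.full(Y.shape[0], np.log(hi))
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    ridge_d = None if X is None else np.zeros(X.shape[1]) if ridge is None else ridge

    def f(logphi):
        phi = np.exp(logphi)[:, None]
        ll = nb_loglik(Y, mu, phi).sum(axis=1)
        if X is not None:
            w = mu / (1.0 + phi * mu)
            A = np.einsum("np,bn,nq->bpq", X, w, X)
            A[:, np.arange(X.shape[1]), np.arange(X.shape[1])] += ridge_d + 1e-10
            ll = ll - 0.5 * np.linalg.slogdet(A)[1]
        return ll

    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        left = fc > fd
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = f(c), f(d)
    return np.exp((a + b) / 2.0)


def nb_glm_batch(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | None = None,
    ridge: np.ndarray | None = None,
    phi: np.ndarray | str | float = "estimate",
    max_iter: int = 100,
    grad_tol: float = 1e-6,
    phi_rounds: int = 6,
    coef_init: np.ndarray | None = None,
    phi_init: np.ndarray | None = None,
    cox_reid: bool = False,
) -> NbBatchFit:
    """Fit NB GLMs for every row of ``Y`` against the shared design ``X``.

    Parameters
    ----------
    Y : (B, n) counts.
    X : (n, p) design.
    offset : scalar, (n,) or (B, n) known log-scale offsets.
    ridge : (p,) non-negative penalties; coefficient j is penalized by
        ridge[j]/2 * b_j^2 (0 = unpenalized).
    phi : "estimate", a scalar, a (B,) vector, or a (B, n) array of fixed
        dispersions. Per-observation dispersions arise when the rows of Y
        are samples and the observations are taxa with their own phi.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Y, off = _as_batch(Y, offset, n)
    B = Y.shape[0]
    ridge = np.zeros(p) if ridge is None else np.asarray(ridge, dtype=float)

    estimate_phi = isinstance(phi, str)
    if estimate_phi:
        if n <= p:
            raise ValueError("dispersion estimation needs more observations than parameters")
        phi_b = np.full(B, 0.1) if phi_init is None else np.asarray(phi_init, dtype=float).copy()
        phi_bn = np.repeat(phi_b[:, None], n, axis=1)
    else:
        phi_arr = np.asarray(phi, dtype=float)
        if phi_arr.ndim == 0:
            phi_bn = np.full((B, n), float(phi_arr))
        elif phi_arr.ndim == 1 and phi_arr.shape[0] == B:
            phi_bn = np.repeat(phi_arr[:, None], n, axis=1)
        else:
            phi_bn = np.broadcast_to(phi_arr, (B, n)).copy()
        phi_b = phi_bn.mean(axis=1)

    all_zero = Y.sum(axis=1) == 0

    # init: warm start when given, else regress log((y + mean)/2) - offset on X
    A0 = X.T @ X + np.diag(np.maximum(ridge, 1e-8))
    if coef_init is not None:
        coef = np.array(coef_init, dtype=float, copy=True)
    else:
        mu0 = (Y + Y.mean(axis=1, keepdims=True)) / 2.0 + 0.1
        z0 = np.log(mu0) - off
        coef = np.linalg.solve(A0, X.T @ z0.T).T  # (B, p)

    converged = np.zeros(B, dtype=bool)
    n_iter = 0
    for round_ in range(phi_rounds if estimate_phi else 1):
        # --- coefficient step: Fisher scoring with step halving
        eta = off + coef @ X.T
        pll, mu = _penalized_ll(Y, eta, phi_bn, ridge, coef)
        for it in range(max_iter):
            n_iter = it + 1
            w = mu / (1.0 + phi_bn * mu)  # (B, n)
            z = (eta - off) + (Y - mu) / mu
            A = np.einsum("np,bn,nq->bpq", X, w, X)
            A[:, np.arange(p), np.arange(p)] += ridge[None, :]
            rhs = np.einsum("np,bn->bp", X, w * z)
            try:
                coef_new = np.linalg.solve(A, rhs[..., None])[..., 0]
            except np.linalg.LinAlgError:
                A[:, np.arange(p), np.arange(p)] += 1e-8
                coef_new = np.linalg.solve(A, rhs[..., None])[..., 0]
            step = np.ones(B)
            delta = coef_new - coef
            for _ in range(20):
                trial = coef + step[:, None] * delta
                eta_t = off + trial @ X.T
                pll_t, mu_t = _penalized_ll(Y, eta_t, phi_bn, ridge, trial)
                bad = pll_t < pll - 1e-10
                if not bad.any():
                    break
                step[bad] *= 0.5
            improved = pll_t >= pll - 1e-10
            coef = np.where(improved[:, None], trial, coef)
            eta = off + coef @ X.T
            pll, mu = _penalized_ll(Y, eta, phi_bn, ridge, coef)
            grad = np.einsum("np,bn->bp", X, (Y - mu) / (1.0 + phi_bn * mu)) - ridge * coef
            converged = np.linalg.norm(grad, axis=1) < grad_tol
            if converged.all():
                break
        # --- dispersion step
        if estimate_phi:
            if cox_reid:
                phi_new = _profile_phi_golden(Y, mu, X=X, ridge=ridge)
            else:
                phi_new = _profile_phi_golden(Y, mu)
                # keep the old value where the search did not actually improve
                worse = (
                    nb_loglik(Y, mu, phi_new[:, None]).sum(axis=1)
                    < nb_loglik(Y, mu, phi_b[:, None]).sum(axis=1)
                )
                phi_new = np.where(worse, phi_b, phi_new)
            rel = np.abs(np.log(phi_new) - np.log(phi_b))
            phi_b = phi_new
            phi_bn = np.repeat(phi_b[:, None], n, axis=1)
            if (rel < 1e-4).all() and round_ > 0:
                break

    # all-zero responses: ridge least-squares toward eta = log(1e-8)
    if all_zero.any():
        target = np.full(n, ZERO_FLOOR_LOG)
        bz = np.linalg.solve(A0, X.T @ (target - 0.0))
        coef[all_zero] = bz
        for idx in np.where(all_zero)[0]:
            eta_z = off[idx] + X @ coef[idx]
            mu[idx] = np.exp(np.clip(eta_z, -ETA_MAX, ETA_MAX))
        converged[all_zero] = True
        if estimate_phi:
            phi_b[all_zero] = 1.0
            phi_bn[all_zero] = 1.0

    loglik = nb_loglik(Y, np.maximum(mu, 1e-300), phi_bn).sum(axis=1)
    return NbBatchFit(coef=coef, phi=phi_b, loglik=loglik, converged=converged, all_zero=all_zero)


def nb_irls_fit(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | None = None,
    ridge: np.ndarray | None = None,
    phi: float | str = "estimate",
) -> NbFit:
    """Fit one ridge-penalized NB GLM (thin wrapper over the batch path).

    Returns coefficients, the (possibly estimated) dispersion and the
    unpenalized log-likelihood at the fit. Non-convergence is flagged on
    the result, never raised.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    fit = nb_glm_batch(y[None, :], X, offset=offset, ridge=ridge, phi=phi)
    return NbFit(
        coef=fit.coef[0],
        phi=float(fit.phi[0]),
        loglik=float(fit.loglik[0]),
        converged=bool(fit.converged[0]),
        n_iter=-1,
    )
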