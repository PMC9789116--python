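"""Negative-binomial factor model for unknown unwanted variation.

Counts y_ij for taxon i in sample j are NB(mu_ij, phi_i) with

    log mu_ij = zeta_i + (M beta_i)_j + (W alpha_i)_j

where M is the known binary sample-to-biological-source membership matrix,
W (N x k) holds unknown sample-level unwanted-factor scores and alpha_i the
taxon-level loadings. Replicate information identifies the loadings (within
a replicate group, count differences are purely technical) and negative
control taxa — taxa with essentially no biological signal — identify the
scores. The model is fitted by alternating ridge-penalized IRLS:

  taxon step   : per taxon, regress y_i on [M | W] (ridge lambda_a on the
                 alpha block only) and profile the dispersion phi_i;
  sample step  : per sample, holding alpha and beta fixed, regress the
                 control-taxa counts on alpha_C with offset zeta_C + (M beta)_C
                 and ridge lambda_b on every W coordinate;
  normalization: center W columns (absorbing the shift into zeta),
                 orthogonalize columns by a scale-preserving QR transform
                 (alpha transformed inversely so the fit is unchanged), and
                 fix signs by positive correlation with the initialization.

Both block updates ascend the joint ridge-penalized log-likelihood, so the
recorded trace is non-decreasing up to tiny normalization slack.

After fitting, counts are corrected by percentile-invariant adjustment: each
observation keeps its percentile under the fitted NB, but the quantile is
re-read from the NB with the unwanted term set to a reference (the W column
mean, zero after centering), yielding integer adjusted counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import nbinom

from .io import ControlSet, CountMatrix, ReplicateMatrix, clr_transform
from .nbglm import nb_glm_batch, nb_loglik

__all__ = ["RuvFit", "AdjustedMatrix", "fit_ruv3nb", "percentile_adjusted_counts"]


@dataclass
class RuvFit:
    """Fitted state of the unwanted-variation factor model."""

    W: np.ndarray  # (N, k), columns centered
    alpha: np.ndarray  # (k, T)
    beta: np.ndarray  # (m, T)
    zeta: np.ndarray  # (T,)
    phi: np.ndarray  # (T,)
    k: int
    lambda_a: float
    lambda_b: float
    converged: bool
    n_iter: int
    penalized_loglik_trace: np.ndarray
    taxa_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    group_ids: list[str] = field(default_factory=list)
    control_taxa: list[str] = field(default_factory=list)
    seed: int | None = None

    def mu(self, M: np.ndarray, reference_w: np.ndarray | None = None) -> np.ndarray:
        """Fitted means (T, N); with ``reference_w`` the W term is replaced by
        a fixed length-k row (the 'adjust to' state)."""
        wterm = (
            self.W @ self.alpha
            if reference_w is None
            else np.broadcast_to(np.asarray(reference_w) @ self.alpha, (self.W.shape[0], self.alpha.shape[1]))
        )
        eta = self.zeta[None, :] + M @ self.beta + wterm  # (N, T)
        return np.exp(np.clip(eta, -30, 30)).T

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        wcols = [f"W{i+1}" for i in range(self.k)]
        pd.DataFrame(self.W, index=self.sample_ids, columns=wcols).to_csv(
            outdir / "W.tsv", sep="\t", index_label="sample_id"
        )
        pd.DataFrame(self.alpha, index=wcols, columns=self.taxa_ids).to_csv(
            outdir / "alpha.tsv", sep="\t", index_label="factor"
        )
        pd.DataFrame(self.beta, index=self.group_ids, columns=self.taxa_ids).to_csv(
            outdir / "beta.tsv", sep="\t", index_label="group"
        )
        pd.DataFrame({"zeta": self.zeta, "phi": self.phi}, index=self.taxa_ids).to_csv(
            outdir / "zeta_phi.tsv", sep="\t", index_label="taxon_id"
        )
        meta = {
            "k": self.k,
            "lambda_a": self.lambda_a,
            "lambda_b": self.lambda_b,
            "seed": self.seed,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "n_controls": len(self.control_taxa),
        }
        (outdir / "fit.json").write_text(json.dumps(meta, indent=2))


@dataclass
class AdjustedMatrix:
    """Percentile-invariant adjusted counts and their log transform."""

    pac: np.ndarray  # (T, N) integers
    log_pac: np.ndarray  # log(pac + 1)
    mode: str
    seed: int | None

    def save(self, outdir, taxa_ids, sample_ids) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.pac, index=taxa_ids, columns=sample_ids).to_csv(
            outdir / "pac.tsv", sep="\t", index_label="taxon_id"
        )
        pd.DataFrame(self.log_pac, index=taxa_ids, columns=sample_ids).to_csv(
            outdir / "log_pac.tsv", sep="\t", index_label="taxon_id"
        )


def _init_W(Y: np.ndarray, M: np.ndarray, ctrl_idx: np.ndarray, k: int) -> np.ndarray:
    """Initialize factor scores: column 1 from log geometric means (depth),
    the rest from an SVD of within-replicate-centered CLR control residuals."""
    N = Y.shape[1]
    g = np.log(Y + 1.0).mean(axis=0)
    w1 = g - g.mean()
    sd = w1.std()
    w1 = w1 / sd if sd > 0 else np.zeros(N)
    W = np.zeros((N, k))
    W[:, 0] = w1
    if k > 1:
        clr = clr_transform(Y)[ctrl_idx]  # (Tc, N)
        group_means = (clr @ M) / M.sum(axis=0)  # (Tc, m)
        resid = (clr - group_means @ M.T).T  # (N, Tc)
        resid -= resid.mean(axis=0, keepdims=True)
        denom = w1 @ w1
        if denom > 0:
            resid -= np.outer(w1, (w1 @ resid) / denom)
        U, s, _ = np.linalg.svd(resid, full_matrices=False)
        for j in range(1, k):
            col = U[:, j - 1]
            col = col - col.mean()
            sd = col.std()
            W[:, j] = col / sd if sd > 0 else col
    return W


def _screen_factors(
    Y: np.ndarray,
    Mmat: np.ndarray,
    ctrl_idx: np.ndarray,
    k: int,
    rng: np.random.Generator,
    n_perm: int = 50,
    percentile: float = 99.0,
) -> int:
    """Number of leading factors with real signal, by Horn's parallel analysis.

    Within-replicate-centered (biology removed), per-taxon standardized log
    control residuals are compared against column-permuted copies of
    themselves: factor j is retained while its singular value exceeds the
    ``percentile`` of the permutation null for the same rank. With no
    unwanted variation in the data every candidate fails the test, so the
    model absorbs nothing.
    """
    L = np.log(Y[ctrl_idx] + 1.0)
    gm = (L @ Mmat) / Mmat.sum(axis=0)
    resid = L - gm @ Mmat.T
    sd = resid.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    R = (resid / sd).T
    R = R - R.mean(axis=0, keepdims=True)
    sv = np.linalg.svd(R, compute_uv=False)
    null_sv = np.empty((n_perm, min(R.shape)))
    P = np.empty_like(R)
    for b in range(n_perm):
        for c in range(R.shape[1]):
            P[:, c] = rng.permutation(R[:, c])
        null_sv[b] = np.linalg.svd(P, compute_uv=False)
    thr = np.percentile(null_sv, percentile, axis=0)
    k_eff = 0
    for j in range(min(k, sv.shape[0])):
        if sv[j] > thr[j]:
            k_eff += 1
        else:
            break
    return k_eff


def _penalized_objective(Y, M, W, alpha, beta, zeta, phi, lambda_a, lambda_b):
    """Control-taxa penalized log-likelihood: the objective both alternating
    steps ascend (the sample step only sees control taxa), and which the SVD
    normalization leaves exactly unchanged. Callers pass control-subset
    slices of Y / alpha / beta / zeta / phi."""
    eta = zeta[None, :] + M @ beta + W @ alpha  # (N, Tc)
    mu = np.exp(np.clip(eta, -30, 30))
    ll = nb_loglik(Y.T, mu, phi[None, :]).sum()
    return ll - 0.5 * lambda_a * (alpha**2).sum() - 0.5 * lambda_b * (W**2).sum()


def fit_ruv3nb(
    cm: CountMatrix,
    M: ReplicateMatrix,
    controls: ControlSet,
    k: int,
    lambda_a: float = 0.01,
    lambda_b: float = 5.0,
    tol: float = 1e-4,
    max_iter: int = 50,
    seed: int | None = 0,
    factor_screen: bool = True,
) -> RuvFit:
    """Fit the NB unwanted-variation factor model.

    Parameters
    ----------
    cm : CountMatrix
        Taxa x samples counts (every sample total > 0).
    M : ReplicateMatrix
        Sample-to-biological-source membership.
    controls : ControlSet
        Negative-control taxa (|controls| >= k); all-zero control taxa are
        dropped with a warning.
    k : int
        Number of unwanted factors.
    lambda_a, lambda_b : float
        Ridge penalties on taxon loadings alpha and sample scores W.
    factor_screen : bool
        Retain only factors that pass a parallel-analysis permutation test
        on the control residuals (default). Screened-out factors are exact
        zero columns of W (and zero loading rows), so on data without
        unwanted variation the adjustment is the identity.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ctrl_ids = sorted(controls.taxa_ids & set(cm.taxa_ids))
    if len(ctrl_ids) < len(controls):
        warnings.warn("some control taxa absent from the matrix; ignored", stacklevel=2)
    Y = cm.counts.astype(float)  # (T, N)
    if (Y.sum(axis=0) == 0).any():
        raise ValueError("every sample must have positive total count")
    ctrl_idx = cm.taxon_index(ctrl_ids)
    nonzero = Y[ctrl_idx].sum(axis=1) > 0
    if not nonzero.all():
        warnings.warn(
            f"dropping {int((~nonzero).sum())} all-zero control taxa", stacklevel=2
        )
        ctrl_idx = ctrl_idx[nonzero]
        ctrl_ids = [t for t, nz in zip(ctrl_ids, nonzero) if nz]
    if len(ctrl_idx) < k:
        raise ValueError(f"need at least k={k} usable control taxa, have {len(ctrl_idx)}")

    T, N = Y.shape
    Mmat = M.matrix
    m = Mmat.shape[1]
    rng = np.random.default_rng(0 if seed is None else seed)
    k_eff = _screen_factors(Y, Mmat, ctrl_idx, k, rng) if factor_screen else k
    phi = np.full(T, 0.1)
    beta = np.zeros((m, T))
    zeta = np.zeros(T)
    trace: list[float] = []
    converged = False
    n_iter = 0

    if k_eff == 0:
        # no evidence of unwanted variation: fit biology only, W stays 0
        tf = nb_glm_batch(Y, Mmat, phi="estimate", max_iter=60)
        zeta = tf.coef.mean(axis=1)
        beta = (tf.coef - zeta[:, None]).T
        phi = tf.phi
        W = np.zeros((N, k))
        alpha = np.zeros((k, T))
        trace.append(
            _penalized_objective(
                Y[ctrl_idx], Mmat, W, alpha[:, ctrl_idx], beta[:, ctrl_idx],
                zeta[ctrl_idx], phi[ctrl_idx], lambda_a, lambda_b,
            )
        )
        return RuvFit(
            W=W, alpha=alpha, beta=beta, zeta=zeta, phi=phi, k=k,
            lambda_a=lambda_a, lambda_b=lambda_b, converged=True, n_iter=1,
            penalized_loglik_trace=np.array(trace),
            taxa_ids=list(cm.taxa_ids), sample_ids=list(cm.sample_ids),
            group_ids=list(M.group_ids), control_taxa=ctrl_ids, seed=seed,
        )

    W = _init_W(Y, Mmat, ctrl_idx, k_eff)
    W_init = W.copy()
    ridge_taxon = np.concatenate([np.zeros(m), np.full(k_eff, lambda_a)])
    alpha = np.zeros((k_eff, T))

    taxon_coef = None
    for it in range(max_iter):
        n_iter = it + 1
        W_old = W.copy()
        # (2) taxon step: y_i on [M | W], ridge on the alpha block only
        X = np.hstack([Mmat, W])
        tf = nb_glm_batch(
            Y,
            X,
            ridge=ridge_taxon,
            phi="estimate",
            max_iter=60,
            coef_init=taxon_coef,
            phi_init=phi if it > 0 else None,
            phi_rounds=6 if it == 0 else 2,
        )
        bg = tf.coef[:, :m]  # (T, m) raw per-group coefficients
        alpha = tf.coef[:, m:].T  # (k, T)
        zeta = bg.mean(axis=1)
        beta = (bg - zeta[:, None]).T  # (m, T)
        phi = tf.phi

        # (3) sample step: control counts per sample on alpha_C
        alpha_C = alpha[:, ctrl_idx].T  # (Tc, k)
        offs = (zeta[ctrl_idx][None, :] + (Mmat @ beta[:, ctrl_idx]))  # (N, Tc)
        sf = nb_glm_batch(
            Y[ctrl_idx].T,  # (N, Tc)
            alpha_C,
            offset=offs,
            ridge=np.full(k_eff, lambda_b),
            phi=np.broadcast_to(phi[ctrl_idx], (N, len(ctrl_idx))),
            max_iter=60,
            coef_init=W,
        )
        W = sf.coef  # (N, k)

        # (4) identifiability: center (absorbed into zeta), then orthogonalize
        # by SVD rotation W = U S V', alpha <- V' alpha. The rotation leaves
        # the fit, ||W||_F and ||alpha||_F all unchanged (both ridges are
        # isotropic), so the penalized objective is exactly invariant, and it
        # orders the columns by explained variance (W1 largest).
        c = W.mean(axis=0)
        W = W - c[None, :]
        zeta = zeta + alpha.T @ c
        U, sv, Vt = np.linalg.svd(W, full_matrices=False)
        W = U * sv[None, :]
        alpha = Vt @ alpha
        for j in range(k_eff):
            if W[:, j] @ W_init[:, j] < 0:
                W[:, j] *= -1
                alpha[j] *= -1

        taxon_coef = np.hstack([(zeta[:, None] + beta.T), alpha.T])  # warm start
        trace.append(
            _penalized_objective(
                Y[ctrl_idx],
                Mmat,
                W,
                alpha[:, ctrl_idx],
                beta[:, ctrl_idx],
                zeta[ctrl_idx],
                phi[ctrl_idx],
                lambda_a,
                lambda_b,
            )
        )
        # (5) convergence on the relative change of W
        delta = np.abs(W - W_old).max() / (1.0 + np.abs(W).max())
        if delta < tol:
            converged = True
            break

    if k_eff < k:  # pad screened-out factors with exact zeros
        W = np.hstack([W, np.zeros((N, k - k_eff))])
        alpha = np.vstack([alpha, np.zeros((k - k_eff, T))])

    return RuvFit(
        W=W,
        alpha=alpha,
        beta=beta,
        zeta=zeta,
        phi=phi,
        k=k,
        lambda_a=lambda_a,
        lambda_b=lambda_b,
        converged=converged,
        n_iter=n_iter,
        penalized_loglik_trace=np.array(trace),
        taxa_ids=list(cm.taxa_ids),
        sample_ids=list(cm.sample_ids),
        group_ids=list(M.group_ids),
        control_taxa=ctrl_ids,
        seed=seed,
    )


def percentile_adjusted_counts(
    fit: RuvFit,
    cm: CountMatrix,
    M: ReplicateMatrix,
    mode: str = "mid",
    seed: int | None = None,
    reference_w: np.ndarray | None = None,
) -> AdjustedMatrix:
    """Percentile-invariant adjusted counts (PAC).

    For each observation, p_ij is taken from the interval
    (F(y_ij - 1), F(y_ij)] of the fitted NB CDF — its midpoint in ``mid``
    mode (deterministic, the default) or a seeded uniform draw in
    ``randomized`` mode — and the adjusted count is the smallest integer
    whose CDF under the reference model (unwanted term at ``reference_w``,
    default the W column means, i.e. zero) reaches p_ij.
    """
    if mode not in ("mid", "randomized"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "randomized" and seed is None:
        raise ValueError("randomized mode requires an explicit seed")
    Y = cm.counts  # (T, N)
    if Y.shape != (len(fit.taxa_ids), len(fit.sample_ids)):
        raise ValueError("fit dimensions do not match the count matrix")
    mu_hat = fit.mu(M.matrix)  # (T, N)
    ref = np.asarray(reference_w, dtype=float) if reference_w is not None else fit.W.mean(axis=0)
    mu_ref = fit.mu(M.matrix, reference_w=ref)
    r = (1.0 / fit.phi)[:, None]
    p_nb = r / (r + mu_hat)
    upper = nbinom.cdf(Y, r, p_nb)
    lower = np.where(Y > 0, nbinom.cdf(Y - 1, r, p_nb), 0.0)
    if mode == "mid":
        p = 0.5 * (lower + upper)
    else:
        rng = np.random.default_rng(seed)
        u = 1.0 - rng.uniform(size=Y.shape)  # (0, 1]: keeps p inside (F(y-1), F(y)]
        p = lower + u * (upper - lower)
    capped = p >= 1.0 - 1e-12
    if capped.any():
        warnings.warn(f"{int(capped.sum())} quantiles capped near 1", stacklevel=2)
        p = np.minimum(p, 1.0 - 1e-12)
    p_ref = r / (r + mu_ref)
    pac = nbinom.ppf(p, r, p_ref)
    pac = np.nan_to_num(pac, nan=0.0, posinf=0.0).astype(np.int64)
    return AdjustedMatrix(pac=pac, log_pac=np.log(pac + 1.0), mode=mode, seed=seed)
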