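"""Correction-quality metrics.

A good correction makes technical replicates look alike and keeps biology
apart. Four views are scored here:

* RLE (relative log expression): per-sample medians and IQRs of deviations
  from each taxon's cross-sample median. Omega_RLE = -ln(V_med + V_iqr)
  aggregates the within-group variances of those summaries (larger =
  better), and NCC_RLE = 1 - total canonical correlation between the RLE
  summaries and known technical factors (larger = less residual batch
  signal).
* PCA + silhouette: average silhouette width on the first PC scores,
  computed per labelling — by biology (higher = preserved) and by batch
  (lower = removed).
* Factor interpretation: correlations of estimated unwanted factors W with
  known experimental factors and numeric covariates.
* Spike-in sanity: mean-CPM ratio between spiked and unspiked samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ControlSet, CountMatrix, factor_names, metadata_for

__all__ = [
    "RleSummary",
    "EvaluationReport",
    "rle_matrix",
    "rle_quality",
    "rle_ncc",
    "pca_scores",
    "silhouette_by_label",
    "factor_correlation",
    "control_cpm_ratio",
    "canonical_correlations",
]

OMEGA_CAP = 1e9  # sentinel for -ln(0)


@dataclass
class RleSummary:
    median: np.ndarray  # per-sample median of RLE
    iqr: np.ndarray  # per-sample IQR of RLE
    grouping: list[str]
    v_med: float
    v_iqr: float
    omega: float
    omega_capped: bool = False


@dataclass
class EvaluationReport:
    rle: RleSummary | None = None
    ncc: float | None = None
    silhouette_by_label: dict[str, float] = field(default_factory=dict)
    factor_correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    pi0: float | None = None

    def to_dict(self) -> dict:
        out: dict = {}
        if self.rle is not None:
            out["rle"] = {
                "v_med": self.rle.v_med,
                "v_iqr": self.rle.v_iqr,
                "omega": self.rle.omega,
                "omega_capped": self.rle.omega_capped,
            }
        if self.ncc is not None:
            out["ncc_rle"] = self.ncc
        out["silhouette"] = dict(self.silhouette_by_label)
        out["factor_correlations"] = {
            f"{w}:{f}": v for (w, f), v in self.factor_correlations.items()
        }
        if self.pi0 is not None:
            out["pi0"] = self.pi0
        return out


def rle_matrix(logm: np.ndarray) -> np.ndarray:
    """Deviations of log values from each taxon's cross-sample median."""
    logm = np.asarray(logm, dtype=float)
    if not np.isfinite(logm).all():
        raise ValueError("log matrix must be finite")
    return logm - np.median(logm, axis=1, keepdims=True)


def rle_quality(rle: np.ndarray, groups: np.ndarray) -> RleSummary:
    """Summarize an RLE matrix into Omega_RLE against a biological grouping.

    Per sample, the median and IQR over taxa are taken; V_med and V_iqr are
    the means over groups (of size >= 2) of the within-group variances of
    those summaries, and Omega = -ln(V_med + V_iqr).
    """
    rle = np.asarray(rle, dtype=float)
    groups = np.asarray(groups)
    med = np.median(rle, axis=0)
    q75, q25 = np.percentile(rle, [75, 25], axis=0)
    iqr = q75 - q25
    v_meds, v_iqrs = [], []
    for g in pd.unique(groups):
        sel = groups == g
        if sel.sum() < 2:
            continue
        v_meds.append(np.var(med[sel], ddof=1))
        v_iqrs.append(np.var(iqr[sel], ddof=1))
    if not v_meds:
        raise ValueError("no group with at least 2 samples")
    v_med = float(np.mean(v_meds))
    v_iqr = float(np.mean(v_iqrs))
    total = v_med + v_iqr
    capped = total <= 0
    omega = OMEGA_CAP if capped else float(-np.log(total))
    return RleSummary(
        median=med,
        iqr=iqr,
        grouping=[str(g) for g in pd.unique(groups)],
        v_med=v_med,
        v_iqr=v_iqr,
        omega=omega,
        omega_capped=capped,
    )


def _dummy_code(md: pd.DataFrame, factors: list[str]) -> np.ndarray:
    """Dummy-code factors dropping reference levels; drop collinear columns."""
    cols = []
    for f in factors:
        d = pd.get_dummies(md[f].astype(str), drop_first=True)
        cols.append(d.to_numpy(dtype=float))
    X = np.hstack(cols) if cols else np.empty((len(md), 0))
    Xc = X - X.mean(axis=0, keepdims=True)
    # drop collinear columns via pivoted QR rank reveal
    if Xc.shape[1] > 1:
        _, r = np.linalg.qr(Xc)
        diag = np.abs(np.diag(r))
        keep = diag > 1e-10 * max(diag.max(), 1.0)
        if not keep.all():
            warnings.warn("dropping collinear factor columns", stacklevel=2)
            Xc = Xc[:, keep]
    return Xc


def canonical_correlations(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Canonical correlations between two column-centered data blocks."""
    Xc = np.asarray(X, float) - np.asarray(X, float).mean(axis=0, keepdims=True)
    Yc = np.asarray(Y, float) - np.asarray(Y, float).mean(axis=0, keepdims=True)

    def _orth(A):
        q, r = np.linalg.qr(A)
        diag = np.abs(np.diag(r))
        keep = diag > 1e-10 * max(diag.max(), 1.0) if diag.size else np.array([], bool)
        return q[:, keep]

    Qx, Qy = _orth(Xc), _orth(Yc)
    if Qx.shape[1] == 0 or Qy.shape[1] == 0:
        return np.zeros(1)
    rho = np.linalg.svd(Qx.T @ Qy, compute_uv=False)
    return np.clip(rho, 0.0, 1.0)


def total_canonical_correlation(X: np.ndarray, Y: np.ndarray) -> float:
    """sqrt(1 - Wilks' Lambda): an aggregate of the canonical correlations,
    equal to the single correlation when only one canonical pair exists."""
    rho = canonical_correlations(X, Y)
    return float(np.sqrt(1.0 - np.prod(1.0 - rho**2)))


def rle_ncc(rle_summary: np.ndarray, md: pd.DataFrame, factors: list[str]) -> float:
    """NCC_RLE = 1 - total canonical correlation between the per-sample RLE
    (median, IQR) summaries and the dummy-coded known technical factors.
    Values near 1 mean the RLE summaries carry no batch signal."""
    S = np.asarray(rle_summary, dtype=float)
    if S.ndim != 2:
        raise ValueError("rle summary must be N x 2 (median, IQR)")
    F = _dummy_code(md, factors)
    if S.shape[0] <= F.shape[1] + S.shape[1]:
        raise ValueError("need more samples than total factor columns")
    return 1.0 - total_canonical_correlation(S, F)


def pca_scores(m: np.ndarray, n_components: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component sample scores of a taxa-by-samples matrix.

    Samples are observations and taxa variables; variables are centered but
    not scaled. Signs follow the convention that each component's largest-
    magnitude loading is positive. Returns (scores N x n, explained-variance
    fractions).
    """
    X = np.asarray(m, dtype=float).T  # samples x taxa
    n = X.shape[0]
    if n <= n_components:
        raise ValueError("need more samples than components")
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        warnings.warn("constant matrix: PCA scores are zero", stacklevel=2)
        return np.zeros((n, n_components)), np.zeros(n_components)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for j in range(min(n_components, Vt.shape[0])):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = (U * s)[:, :n_components]
    explained = (s**2 / (s**2).sum())[:n_components]
    return scores, explained


def silhouette_by_label(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average silhouette width with Euclidean distances.

    Singleton-label samples and exact ties (a = b = 0) score 0.
    """
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 labels")
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    n = X.shape[0]
    s = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i])
        n_same = same.sum() - 1
        if n_same == 0:
            continue  # singleton: s = 0
        a = d[i, same].sum() / n_same
        b = min(d[i, labels == g].mean() for g in uniq if g != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def factor_correlation(
    W: np.ndarray,
    md: pd.DataFrame,
    numeric_covariates: dict[str, np.ndarray] | None = None,
) -> dict[tuple[str, str], float]:
    """Correlate each estimated unwanted factor with known factors.

    Categorical metadata factors use the canonical correlation between the
    W column and the dummy-coded factor (in [0, 1]); numeric covariates
    (e.g. log library size, log geometric mean) use signed Pearson r.
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.shape[0] < W.shape[1]:
        W = W.T
    out: dict[tuple[str, str], float] = {}
    for j in range(W.shape[1]):
        w = W[:, j]
        name = f"W{j+1}"
        degenerate = np.std(w) == 0
        for f in factor_names(md):
            if degenerate:
                out[(name, f)] = 0.0
                continue
            F = _dummy_code(md, [f])
            out[(name, f)] = total_canonical_correlation(w[:, None], F)
        for cov, vals in (numeric_covariates or {}).items():
            vals = np.asarray(vals, dtype=float)
            if not np.isfinite(vals).all():
                raise ValueError(f"numeric covariate {cov!r} must be finite")
            if degenerate or np.std(vals) == 0:
                out[(name, cov)] = 0.0
            else:
                out[(name, cov)] = float(np.corrcoef(w, vals)[0, 1])
    return out


def control_cpm_ratio(
    cm: CountMatrix, md: pd.DataFrame, taxa: ControlSet
) -> pd.Series:
    """Per-taxon ratio of mean CPM in spiked vs unspiked samples.

    Spike-in taxa are expected to show ratios far above 1 (the screening
    rule in the source experiment used a 46-fold margin); an undefined 0/0
    ratio is returned as NaN and a positive/0 ratio as +inf.
    """
    rows = metadata_for(md, cm.sample_ids)
    if "spiked" not in rows.columns:
        raise ValueError("metadata has no spiked flag")
    spiked = rows["spiked"].to_numpy().astype(bool)
    if spiked.all() or (~spiked).all():
        raise ValueError("spiked flag does not partition the samples")
    cpm = cm.counts / cm.library_sizes * 1e6
    idx = cm.taxon_index(sorted(taxa.taxa_ids & set(cm.taxa_ids)))
    names = [cm.taxa_ids[i] for i in idx]
    mean_sp = cpm[np.ix_(idx, np.where(spiked)[0])].mean(axis=1)
    mean_un = cpm[np.ix_(idx, np.where(~spiked)[0])].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mean_sp / mean_un
    return pd.Series(ratio, index=names, name="cpm_ratio")
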