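"""Linear control-feature baselines for unwanted-variation removal.

Both operate on a log-scale matrix (CLR-transformed counts in the standard
workflow) and estimate unwanted-factor sample scores from the control taxa:
RUVg from the row-centered control submatrix directly, RUVs after
additionally centering the controls within replicate groups so that
biological differences between groups cannot leak into the factors. The
adjustment regresses every taxon on the estimated scores and subtracts the
fitted component.
"""

from __future__ import annotations

import numpy as np

from .io import ControlSet, ReplicateMatrix

__all__ = ["ruvg", "ruvs"]


def _control_submatrix(logm: np.ndarray, controls: ControlSet, taxa_ids: list[str]) -> np.ndarray:
    pos = {t: i for i, t in enumerate(taxa_ids)}
    idx = [pos[t] for t in sorted(controls.taxa_ids) if t in pos]
    if not idx:
        raise ValueError("no control taxa present in the matrix")
    return logm[np.array(idx)]


def _factor_scores(centered: np.ndarray, k: int) -> np.ndarray:
    """First k right-singular directions (sample scores) of a centered
    controls-by-samples matrix."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rank = np.linalg.matrix_rank(centered)
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank {rank} of the control submatrix")
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    return (Vt[:k] * s[:k, None]).T  # N x k


def _adjust(logm: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Subtract each taxon's least-squares projection on W (rows centered
    for the regression; the row means stay in the output)."""
    rowmean = logm.mean(axis=1, keepdims=True)
    Xc = logm - rowmean
    coef = np.linalg.lstsq(W, Xc.T, rcond=None)[0]  # k x T
    return logm - (W @ coef).T


def ruvg(
    logm: np.ndarray, controls: ControlSet, taxa_ids: list[str], k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Control-feature factor baseline on a log matrix.

    Returns (W sample scores N x k, adjusted matrix T x N).
    """
    logm = np.asarray(logm, dtype=float)
    if not np.isfinite(logm).all():
        raise ValueError("log matrix must be finite")
    C = _control_submatrix(logm, controls, taxa_ids)
    Cc = C - C.mean(axis=1, keepdims=True)
    W = _factor_scores(Cc, k)
    return W, _adjust(logm, W)


def ruvs(
    logm: np.ndarray,
    controls: ControlSet,
    taxa_ids: list[str],
    M: ReplicateMatrix,
    k: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate-aware control-feature baseline.

    Control rows are centered within each replicate group (removing
    biology) before the factor extraction; otherwise as :func:`ruvg`.
    """
    logm = np.asarray(logm, dtype=float)
    if not np.isfinite(logm).all():
        raise ValueError("log matrix must be finite")
    if (M.group_sizes() < 2).all():
        raise ValueError("RUVs needs at least one replicate group of size >= 2")
    C = _control_submatrix(logm, controls, taxa_ids)
    Mm = M.matrix
    group_means = (C @ Mm) / Mm.sum(axis=0)
    Cc = C - group_means @ Mm.T
    W = _factor_scores(Cc, k)
    return W, _adjust(logm, W)
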