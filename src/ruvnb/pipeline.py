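"""End-to-end benchmarking: correct a count matrix with each configured
method and score every correction with the same metric panel.

Methods: the NB factor model (fit + log percentile-adjusted counts), the
linear RUVg/RUVs baselines on CLR-transformed counts, the uncorrected CLR
matrix as reference, and any externally corrected log matrix supplied
through the TSV interface. The output is a tidy method-by-metric table:
Omega_RLE, NCC_RLE, silhouette by biology and by each technical factor,
and (when a null contrast is given) Storey's pi0 with and without W
covariates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import baselines
from .diffabund import nb_da_test
from .evaluation import (
    factor_correlation,
    pca_scores,
    rle_matrix,
    rle_ncc,
    rle_quality,
    silhouette_by_label,
)
from .io import ControlSet, CountMatrix, build_replicate_matrix, clr_transform, factor_names, metadata_for
from .ruv import fit_ruv3nb, percentile_adjusted_counts

__all__ = ["benchmark", "BenchmarkResult", "write_manifest"]


@dataclass
class BenchmarkResult:
    metrics: pd.DataFrame  # method x metric
    W: dict[str, np.ndarray]  # per-method estimated factors (where defined)
    corrected: dict[str, np.ndarray]  # per-method corrected log matrix
    factor_correlations: dict[str, dict] | None = None


def _score(
    logm: np.ndarray,
    md_rows: pd.DataFrame,
    bio_groups: np.ndarray,
    tech_factors: list[str],
) -> dict[str, float]:
    rle = rle_matrix(logm)
    summary = rle_quality(rle, bio_groups)
    out = {
        "omega_rle": summary.omega,
        "v_med": summary.v_med,
        "v_iqr": summary.v_iqr,
    }
    if tech_factors:
        out["ncc_rle"] = rle_ncc(
            np.column_stack([summary.median, summary.iqr]), md_rows, tech_factors
        )
    scores, _ = pca_scores(logm, n_components=4)
    out["silhouette_biology"] = silhouette_by_label(scores, bio_groups)
    for f in tech_factors:
        out[f"silhouette_{f}"] = silhouette_by_label(
            scores, md_rows[f].to_numpy()
        )
    return out


def benchmark(
    cm: CountMatrix,
    md: pd.DataFrame,
    controls: ControlSet,
    k: int = 7,
    seed: int = 0,
    methods: tuple[str, ...] = ("clr", "ruv3nb", "ruvg", "ruvs"),
    external: dict[str, np.ndarray] | None = None,
    null_contrast: str | None = None,
    tech_factors: list[str] | None = None,
) -> BenchmarkResult:
    """Run every configured correction method and score it.

    ``k`` defaults to 7 but is lowered to |controls| - 1 (with a notice)
    when the control set is too small to support it. ``null_contrast``
    names a metadata factor expected to carry no biology (a technical
    contrast within biological groups); pi0 of that contrast is reported
    with the method's W as covariates where W exists.
    """
    md_rows = metadata_for(md, cm.sample_ids)
    bio = md_rows["replicate_group"].to_numpy()
    if tech_factors is None:
        tech_factors = factor_names(md_rows)
    controls = controls.restrict(cm)
    if len(controls) <= k:
        import logging

        logging.getLogger(__name__).info(
            "lowering k from %d to %d (= |controls| - 1)", k, len(controls) - 1
        )
        k = len(controls) - 1
    M = build_replicate_matrix(md_rows, cm.sample_ids)
    clr = clr_transform(cm)

    rows: dict[str, dict] = {}
    Ws: dict[str, np.ndarray] = {}
    corrected: dict[str, np.ndarray] = {}
    for method in methods:
        if method == "clr":
            logm = clr
        elif method == "ruv3nb":
            fit = fit_ruv3nb(cm, M, controls, k=k, seed=seed)
            adj = percentile_adjusted_counts(fit, cm, M)
            logm = adj.log_pac
            Ws[method] = fit.W
        elif method == "ruvg":
            W, logm = baselines.ruvg(clr, controls, cm.taxa_ids, k)
            Ws[method] = W
        elif method == "ruvs":
            W, logm = baselines.ruvs(clr, controls, cm.taxa_ids, M, k)
            Ws[method] = W
        else:
            raise ValueError(f"unknown method {method!r}")
        corrected[method] = logm
        rows[method] = _score(logm, md_rows, bio, tech_factors)
    for name, logm in (external or {}).items():
        if logm.shape != (cm.n_taxa, cm.n_samples):
            raise ValueError(f"external matrix {name!r} has wrong shape")
        corrected[name] = logm
        rows[name] = _score(logm, md_rows, bio, tech_factors)

    if null_contrast is not None:
        # technical contrast within the first biological group (the
        # frozen-vs-unfrozen-within-one-source design): no biology differs,
        # so pi0 near 1 indicates a specific correction
        sel = bio == pd.unique(bio)[0]
        sub = cm.subset_samples([s for s, in_g in zip(cm.sample_ids, sel) if in_g])
        labels = md_rows.loc[sel, null_contrast].to_numpy()
        contrast = labels == pd.unique(labels)[0]
        base = nb_da_test(sub, contrast)
        for method in rows:
            if method in Ws:
                rows[method]["pi0_null_contrast"] = nb_da_test(
                    sub, contrast, covariates=Ws[method][sel]
                ).pi0
            else:
                rows[method]["pi0_null_contrast"] = base.pi0

    metrics = pd.DataFrame(rows).T
    metrics.index.name = "method"
    fcorr = {
        m: {f"{a}:{b}": v for (a, b), v in factor_correlation(W, md_rows).items()}
        for m, W in Ws.items()
    }
    return BenchmarkResult(metrics=metrics, W=Ws, corrected=corrected, factor_correlations=fcorr)


def write_manifest(outdir, seed: int, params: dict, inputs: dict[str, Path] | None = None) -> Path:
    """Record how a run was produced: seed, parameters, input checksums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "params": params, "inputs": {}}
    for name, path in (inputs or {}).items():
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        manifest["inputs"][name] = {"path": str(path), "sha256": digest}
    out = outdir / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
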