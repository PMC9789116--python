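"""Synthetic metagenome count matrices with known unwanted structure.

The generator emulates the statistical shape of a replicated spike-in
experiment: a few biological sources each sequenced as many technical
replicates, NB-distributed counts with taxon-specific dispersion, a dominant
sequencing-depth factor plus batch-like unwanted factors (storage condition,
library kit, ...), taxon classes with factor-specific sensitivity, designated
negative-control taxa with zero biological signal, spike-in taxa elevated
only in spiked samples, and high sparsity. Full ground truth (W, alpha,
beta, zeta, phi, control/spike flags, class labels) is returned so every
pipeline stage can be scored against known values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ControlSet,
    CountMatrix,
    Provenance,
    build_replicate_matrix,
    write_control_list,
    write_counts,
)

__all__ = ["SyntheticTruth", "simulate_experiment", "write_scenario", "default_scenario"]

DEFAULT_BATCH_FACTORS = (("storage", 2, 1.0), ("kit", 2, 0.7))
TAXON_CLASSES = ("Bacilli", "Clostridia", "Bacteroidia", "Gammaproteobacteria", "Actinomycetia")


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated count matrix."""

    W_true: np.ndarray  # (N, k)
    alpha_true: np.ndarray  # (k, T)
    beta_true: np.ndarray  # (m, T)
    zeta_true: np.ndarray  # (T,)
    phi_true: np.ndarray  # (T,)
    control_flags: np.ndarray  # (T,) bool, beta == 0
    spike_flags: np.ndarray  # (T,) bool
    class_labels: list[str]  # per taxon
    metadata: pd.DataFrame
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def control_taxa(self) -> list[str]:
        return [t for t, f in zip(self.params["taxa_ids"], self.control_flags) if f]

    @property
    def spike_taxa(self) -> list[str]:
        return [t for t, f in zip(self.params["taxa_ids"], self.spike_flags) if f]

    def control_set(self, include_spikes: bool = True) -> ControlSet:
        ids = set(self.control_taxa)
        if not include_spikes:
            ids -= set(self.spike_taxa)
        return ControlSet(frozenset(ids), Provenance.spike_in)


def _balanced_levels(n: int, levels: list[str], rng: np.random.Generator) -> np.ndarray:
    """Random assignment of ``levels`` to n slots, as balanced as possible."""
    reps = int(np.ceil(n / len(levels)))
    arr = np.array((levels * reps)[:n])
    rng.shuffle(arr)
    return arr


def _expected_zero_fraction(eta: np.ndarray, phi: np.ndarray) -> float:
    mu = np.exp(np.clip(eta, -30, 30))
    r = (1.0 / phi)[:, None]
    return float(np.mean(np.exp(-r * np.log1p(mu / r))))


def simulate_experiment(
    n_groups: int = 2,
    reps_per_group: int = 20,
    T: int = 400,
    k: int = 3,
    n_controls: int = 80,
    n_spikes: int = 8,
    batch_factors=DEFAULT_BATCH_FACTORS,
    depth_sd: float = 0.5,
    sparsity_target: float = 0.6,
    phi_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    bio_sd: float = 1.2,
    bio_floor: float = 0.0,
    zeta_scale: float = 2.0,
    dominant_mask_p: float = 0.9,
    background_mask_p: float = 0.3,
    spike_ratio: float = 50.0,
    spike_fraction: float = 1.0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Simulate a replicated experiment with layered unwanted variation.

    ``k`` counts the depth factor plus the batch factors, so it must be at
    least ``1 + len(batch_factors)``; any excess columns are pure-noise
    factors. The abundance spectrum (zeta) is log-normal with its location
    calibrated by bisection so the expected zero fraction matches
    ``sparsity_target`` within 0.05.

    Returns the counts and a :class:`SyntheticTruth` carrying every model
    parameter, flags for the beta=0 control taxa and the spike-ins, taxon
    class labels, and the sample metadata (replicate group, batch factor
    levels, spiked flag).
    """
    if n_controls + n_spikes > T:
        raise ValueError("n_controls + n_spikes must not exceed T")
    batch_factors = list(batch_factors)
    if k < 1 + len(batch_factors):
        raise ValueError("k must cover the depth factor plus every batch factor")
    rng = np.random.default_rng(seed)
    N = n_groups * reps_per_group
    m = n_groups
    group_ids = [f"P{g+1}" for g in range(m)]
    sample_ids = [f"S{j+1:03d}" for j in range(N)]
    taxa_ids = [f"tax{i+1:04d}" for i in range(T)]
    group_of = np.repeat(np.arange(m), reps_per_group)

    # ---- sample-level structure
    md = pd.DataFrame({"sample_id": sample_ids, "replicate_group": [group_ids[g] for g in group_of]})
    W = np.zeros((N, k))
    log_depth = rng.normal(0.0, depth_sd, size=N) if depth_sd > 0 else np.zeros(N)
    w1 = log_depth - log_depth.mean()
    W[:, 0] = w1 / w1.std() if w1.std() > 0 else 0.0
    col = 1
    for name, n_levels, _scale in batch_factors:
        levels = [f"{name}{l+1}" for l in range(n_levels)]
        assigned = np.concatenate(
            [_balanced_levels(reps_per_group, levels, rng) for _ in range(m)]
        )
        md[name] = assigned
        # standardized dummy of the first level contrast (2-level factors) or
        # a standardized level-score for >2 levels
        codes = pd.Categorical(assigned, categories=levels).codes.astype(float)
        codes -= codes.mean()
        sd = codes.std()
        W[:, col] = codes / sd if sd > 0 else 0.0
        col += 1
    for j in range(col, k):  # spare columns: pure noise factors
        z = rng.normal(size=N)
        z -= z.mean()
        W[:, j] = z / z.std()
    # Spiking status. The default (all samples spiked) mirrors benchmark
    # analyses being run on spiked samples only: when only a fraction of
    # samples receives the spike-in mix, the spike indicator acts as an
    # additional latent technical factor that is NOT part of W_true.
    n_spiked = int(round(spike_fraction * reps_per_group))
    spiked_parts = []
    for _ in range(m):
        flags = np.array([True] * n_spiked + [False] * (reps_per_group - n_spiked))
        rng.shuffle(flags)
        spiked_parts.append(flags)
    md["spiked"] = np.concatenate(spiked_parts)

    # ---- taxon-level structure
    classes = [TAXON_CLASSES[i] for i in rng.integers(0, len(TAXON_CLASSES), size=T)]
    is_spike = np.zeros(T, dtype=bool)
    is_spike[:n_spikes] = True
    is_control = np.zeros(T, dtype=bool)
    is_control[: n_controls] = True  # spikes are a subset of the beta=0 taxa
    phi = rng.uniform(phi_range[0], phi_range[1], size=T)
    beta = rng.normal(0.0, bio_sd, size=(m, T))
    beta -= beta.mean(axis=0, keepdims=True)
    if bio_floor > 0:
        # "strong biology": every non-control taxon's between-group spread
        # is bounded below by 2*bio_floor (scaling the centered deviations)
        spread = beta.max(axis=0) - beta.min(axis=0)
        beta *= np.maximum(1.0, 2.0 * bio_floor / np.maximum(spread, 1e-12))
    beta[:, is_control] = 0.0

    alpha = np.zeros((k, T))
    alpha[0] = depth_sd * rng.normal(1.0, 0.05, size=T)  # depth loads on everything
    for f, (name, _lv, scale) in enumerate(batch_factors, start=1):
        dominant = TAXON_CLASSES[(f - 1) % len(TAXON_CLASSES)]
        p_mask = np.where(np.array(classes) == dominant, dominant_mask_p, background_mask_p)
        mask = rng.uniform(size=T) < p_mask
        alpha[f] = mask * rng.normal(0.0, scale, size=T)
    # spare noise factors get weak diffuse loadings
    for f in range(1 + len(batch_factors), k):
        alpha[f] = rng.normal(0.0, 0.1, size=T)

    # ---- abundance spectrum calibrated to the sparsity target
    zeta_raw = rng.normal(0.0, zeta_scale, size=T)
    M = np.zeros((N, m))
    M[np.arange(N), group_of] = 1.0
    eta_base = (M @ beta + W @ alpha).T  # (T, N)
    lo, hi = -10.0, 15.0
    loc = 2.0
    for _ in range(20):
        frac = _expected_zero_fraction(eta_base + (zeta_raw + loc)[:, None], phi)
        if abs(frac - sparsity_target) < 0.01:
            break
        if frac > sparsity_target:
            lo = loc
        else:
            hi = loc
        loc = 0.5 * (lo + hi)
    else:
        frac = _expected_zero_fraction(eta_base + (zeta_raw + loc)[:, None], phi)
        if abs(frac - sparsity_target) > 0.05:
            raise ValueError(
                f"could not calibrate sparsity: target {sparsity_target}, reached {frac:.3f}"
            )
    zeta = zeta_raw + loc
    # spike-ins: elevated base abundance, present at full level only in spiked samples
    zeta[is_spike] = np.log(np.exp(zeta[is_spike]).mean() * 5.0 + 50.0)
    eta = eta_base + zeta[:, None]
    unspiked_cols = ~md["spiked"].to_numpy()
    eta[np.ix_(is_spike, unspiked_cols)] -= np.log(spike_ratio)

    mu = np.exp(np.clip(eta, -30, 30))
    r = (1.0 / phi)[:, None]
    counts = rng.negative_binomial(r, r / (r + mu))

    cm = CountMatrix(taxa_ids, sample_ids, counts)
    truth = SyntheticTruth(
        W_true=W,
        alpha_true=alpha,
        beta_true=beta,
        zeta_true=zeta,
        phi_true=phi,
        control_flags=is_control,
        spike_flags=is_spike,
        class_labels=classes,
        metadata=md,
        seed=seed,
        params={
            "n_groups": n_groups,
            "reps_per_group": reps_per_group,
            "T": T,
            "k": k,
            "n_controls": n_controls,
            "n_spikes": n_spikes,
            "batch_factors": [list(b) for b in batch_factors],
            "depth_sd": depth_sd,
            "sparsity_target": sparsity_target,
            "phi_range": list(phi_range),
            "bio_sd": bio_sd,
            "zeta_scale": zeta_scale,
            "dominant_mask_p": dominant_mask_p,
            "background_mask_p": background_mask_p,
            "spike_ratio": spike_ratio,
            "spike_fraction": spike_fraction,
            "taxa_ids": taxa_ids,
            "sample_ids": sample_ids,
        },
    )
    return cm, truth


def default_scenario(seed: int = 0) -> tuple[CountMatrix, SyntheticTruth]:
    """The default study conditions: 2 biological sources x 20 technical
    replicates, 400 taxa, depth + storage + kit unwanted factors, 80
    negative-control taxa of which 8 are spike-ins."""
    return simulate_experiment(seed=seed)


def write_scenario(cm: CountMatrix, truth: SyntheticTruth, outdir, force: bool = False) -> None:
    """Serialize a simulated scenario: counts.tsv, metadata.tsv,
    controls_true.txt, truth/ tables, scenario.json."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists; pass force=True to overwrite")
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    write_counts(cm, outdir / "counts.tsv")
    truth.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    write_control_list(truth.control_set(), outdir / "controls_true.txt")
    wcols = [f"W{i+1}" for i in range(truth.W_true.shape[1])]
    pd.DataFrame(truth.W_true, index=cm.sample_ids, columns=wcols).to_csv(
        outdir / "truth" / "W_true.tsv", sep="\t", index_label="sample_id"
    )
    pd.DataFrame(truth.alpha_true, index=wcols, columns=cm.taxa_ids).to_csv(
        outdir / "truth" / "alpha.tsv", sep="\t", index_label="factor"
    )
    pd.DataFrame(
        truth.beta_true,
        index=sorted(set(truth.metadata["replicate_group"]), key=list(truth.metadata["replicate_group"]).index),
        columns=cm.taxa_ids,
    ).to_csv(outdir / "truth" / "beta.tsv", sep="\t", index_label="group")
    pd.DataFrame(
        {
            "zeta": truth.zeta_true,
            "phi": truth.phi_true,
            "control": truth.control_flags,
            "spike": truth.spike_flags,
            "class": truth.class_labels,
        },
        index=cm.taxa_ids,
    ).to_csv(outdir / "truth" / "taxa.tsv", sep="\t", index_label="taxon_id")
    params = {key: val for key, val in truth.params.items() if key not in ("taxa_ids", "sample_ids")}
    params["seed"] = truth.seed
    (outdir / "scenario.json").write_text(json.dumps(params, indent=2))
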