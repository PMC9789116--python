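"""Empirical negative-control taxa identification.

Negative controls anchor the factor model: they are taxa believed to carry
no biological signal of interest, so any variation they show is technical.
Besides spike-ins, two data-driven selection procedures are provided:

* a *biological-contrast* procedure for designs with few biological groups
  and (optionally) spiked/unspiked samples: taxa least differentially
  abundant between biological groups, refined to those least affected by
  the spiking process;
* a *permutation* procedure for designs with many small replicate groups:
  taxa consistently least differentially abundant between random,
  factor-balanced hypothetical sample splits, intersected over repeats and
  over factors.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .diffabund import moderate_dispersion, nb_da_test
from .io import ControlSet, CountMatrix, Provenance, factor_names, metadata_for
from .nbglm import nb_glm_batch

__all__ = [
    "empirical_controls_biological",
    "empirical_controls_permutation",
    "combine_controls",
]

logger = logging.getLogger(__name__)


def _highest_p_taxa(res, n_keep: int) -> set[str]:
    """The n_keep taxa with the highest p-values (ties broken by taxon id)."""
    order = sorted(zip(res.taxa_ids, res.pvalue), key=lambda tp: (-tp[1], tp[0]))
    return {t for t, _ in order[:n_keep]}


def _lowest_p_taxa(res, n_drop: int) -> set[str]:
    order = sorted(zip(res.taxa_ids, res.pvalue), key=lambda tp: (tp[1], tp[0]))
    return {t for t, _ in order[:n_drop]}


def empirical_controls_biological(
    cm: CountMatrix,
    md: pd.DataFrame,
    n_keep: int = 1000,
    spike_exclude_fraction: float = 0.15,
) -> ControlSet:
    """Empirical controls from the biological contrast, spike-refined.

    (a) Test taxa between biological replicate groups (unadjusted) and keep
    the ``n_keep`` with the highest p-values — least biological signal.
    (b) If spiked and unspiked samples exist within groups, per group test
    spiked vs unspiked and drop the ``spike_exclude_fraction`` most affected
    taxa; intersect the survivors across groups. Return the intersection of
    (a) and (b).
    """
    rows = metadata_for(md, cm.sample_ids)
    groups = rows["replicate_group"].to_numpy()
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 replicate groups for the biological contrast")
    in_first = groups == levels[0]
    res = nb_da_test(cm, in_first)
    n_keep = min(n_keep, cm.n_taxa)
    kept = _highest_p_taxa(res, n_keep)

    has_spike = "spiked" in rows.columns and rows["spiked"].nunique() == 2
    if not has_spike or spike_exclude_fraction <= 0:
        if not has_spike:
            logger.info("no spiked/unspiked partition; skipping spike refinement")
        return ControlSet(frozenset(kept), Provenance.empirical)

    survivors_per_group = []
    for level in levels:
        sel = groups == level
        sub = cm.subset_samples([s for s, m in zip(cm.sample_ids, sel) if m])
        spiked = rows.loc[sel, "spiked"].to_numpy().astype(bool)
        if spiked.all() or (~spiked).all():
            raise ValueError(f"spiked flag does not partition samples in group {level}")
        res_g = nb_da_test(sub, spiked)
        n_drop = math.ceil(spike_exclude_fraction * sub.n_taxa)
        survivors_per_group.append(set(sub.taxa_ids) - _lowest_p_taxa(res_g, n_drop))
    refined = set.intersection(*survivors_per_group)
    final = kept & refined
    if not final:
        raise ValueError(
            "empty control set after spike refinement; increase n_keep or "
            "reduce spike_exclude_fraction"
        )
    return ControlSet(frozenset(final), Provenance.empirical)


def _balanced_split(
    levels: np.ndarray, rng: np.random.Generator, parity: int
) -> tuple[np.ndarray, int]:
    """Random two-way split of samples balancing the counts of each level;
    odd leftovers alternate between the groups (``parity`` tracks the turn)."""
    assign = np.zeros(levels.shape[0], dtype=bool)
    for level in pd.unique(levels):
        idx = np.where(levels == level)[0]
        rng.shuffle(idx)
        half = idx.size // 2
        assign[idx[:half]] = True
        if idx.size % 2:
            assign[idx[half]] = bool(parity % 2)
            parity += 1
    return assign, parity


def empirical_controls_permutation(
    cm: CountMatrix,
    md: pd.DataFrame,
    factors: list[str] | None = None,
    n_perm: int = 10,
    keep_fraction: float = 0.75,
    seed: int = 0,
) -> ControlSet:
    """Empirical controls from repeated factor-balanced random splits.

    For each factor of interest: ``n_perm`` times, split the samples into
    two hypothetical groups with the factor's levels balanced across the
    split, test between the hypothetical groups, and keep the
    ``ceil(keep_fraction * T)`` taxa with the highest p-values; intersect
    the kept sets over the repeats. Finally intersect over factors. Taxa
    genuinely associated with a factor land in the imbalance of some splits
    and are eliminated.
    """
    rows = metadata_for(md, cm.sample_ids)
    if factors is None:
        factors = factor_names(rows)
    if not factors:
        raise ValueError("no factors of interest given or found in metadata")
    if cm.n_samples < 4:
        raise ValueError("need at least 4 samples")
    rng = np.random.default_rng(seed)
    n_keep = math.ceil(keep_fraction * cm.n_taxa)
    # Dispersion is estimated once, under the replicate-group design, and
    # held fixed across all hypothetical splits: estimating it per split
    # would let genuine group structure (balanced across a split) inflate
    # the dispersion and hide as stably conservative p-values.
    Y = cm.counts.astype(float)
    groups_dummy = pd.get_dummies(rows["replicate_group"]).to_numpy(dtype=float)
    lib = Y.sum(axis=0)
    est = nb_glm_batch(
        Y, groups_dummy, offset=np.log(lib), phi="estimate", max_iter=60, cox_reid=True
    )
    phi_fixed = moderate_dispersion(
        est.phi, np.log(Y.mean(axis=1) + 0.5),
        df_resid=cm.n_samples - groups_dummy.shape[1],
    )
    per_factor: list[set[str]] = []
    for factor in factors:
        if rows[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has fewer than 2 levels")
        levels = rows[factor].to_numpy()
        kept: set[str] | None = None
        parity = 0
        for _ in range(n_perm):
            split, parity = _balanced_split(levels, rng, parity)
            res = nb_da_test(cm, split, dispersion=phi_fixed)
            top = _highest_p_taxa(res, n_keep)
            kept = top if kept is None else kept & top
        per_factor.append(kept)
    final = set.intersection(*per_factor)
    if not final:
        raise ValueError(
            "empty control set; increase keep_fraction or reduce n_perm"
        )
    return ControlSet(frozenset(final), Provenance.empirical)


def combine_controls(
    spikes: ControlSet | None,
    empirical: ControlSet | None,
    cm: CountMatrix | None = None,
) -> ControlSet:
    """Union of spike-in and empirical control sets, restricted to the
    analysis matrix when one is given."""
    if spikes is None and empirical is None:
        raise ValueError("at least one control set is required")
    ids: set[str] = set()
    if spikes is not None:
        ids |= spikes.taxa_ids
    if empirical is not None:
        ids |= empirical.taxa_ids
    prov = (
        Provenance.combined
        if spikes is not None and empirical is not None
        else (spikes or empirical).provenance
    )
    out = ControlSet(frozenset(ids), prov)
    if cm is not None:
        out = out.restrict(cm)
        out = ControlSet(out.taxa_ids, prov)
    return out
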