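"""Input/output and compositional preprocessing for taxon-count matrices.

The universal input is a taxa-by-samples matrix of non-negative integer
sequencing counts, accompanied by per-sample metadata (a replicate/biological
group, named experimental factors such as storage condition or library kit,
and an optional ``spiked`` flag) and plain-text lists of negative-control
taxa. Counts travel as TSV/CSV with taxa in rows by default; a flag accepts
the transposed layout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ReplicateMatrix",
    "ControlSet",
    "Provenance",
    "read_counts",
    "write_counts",
    "read_metadata",
    "validate_metadata",
    "read_control_list",
    "write_control_list",
    "filter_by_cpm",
    "clr_transform",
    "tss_normalize",
    "build_replicate_matrix",
]


class CountMatrixFormatError(ValueError):
    """Malformed count table (duplicate ids, bad shape)."""


@dataclass(frozen=True)
class CountMatrix:
    """Taxa x samples matrix of non-negative integer counts.

    Parameters
    ----------
    taxa_ids : list of str
        Row identifiers, unique.
    sample_ids : list of str
        Column identifiers, unique.
    counts : ndarray of shape (T, N)
        Non-negative integers.
    """

    taxa_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise CountMatrixFormatError("counts must be a 2-D array")
        t, n = counts.shape
        if t < 1 or n < 2:
            raise CountMatrixFormatError(
                f"need at least 1 taxon and 2 samples, got {t} x {n}"
            )
        if len(self.taxa_ids) != t or len(self.sample_ids) != n:
            raise CountMatrixFormatError("id lists do not match matrix shape")
        if len(set(self.taxa_ids)) != t:
            raise CountMatrixFormatError("duplicate taxa ids")
        if len(set(self.sample_ids)) != n:
            raise CountMatrixFormatError("duplicate sample ids")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integral")
            counts = np.round(counts).astype(np.int64)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "taxa_ids", list(self.taxa_ids))
        object.__setattr__(self, "sample_ids", list(self.sample_ids))

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample total counts (column sums)."""
        return self.counts.sum(axis=0)

    def taxon_index(self, taxa: Iterable[str]) -> np.ndarray:
        pos = {t: i for i, t in enumerate(self.taxa_ids)}
        try:
            return np.array([pos[t] for t in taxa], dtype=int)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"taxon {exc.args[0]!r} not in matrix") from exc

    def subset_taxa(self, taxa: Sequence[str]) -> "CountMatrix":
        idx = self.taxon_index(taxa)
        return CountMatrix(list(taxa), self.sample_ids, self.counts[idx])

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in samples], dtype=int)
        return CountMatrix(self.taxa_ids, list(samples), self.counts[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxa_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class ReplicateMatrix:
    """Binary N x m membership matrix linking samples to biological sources.

    Row p has a single 1 in the column of sample p's replicate group; this is
    the design the factor model uses to separate biology (shared within a
    group) from technical variation (differing between replicates).
    """

    matrix: np.ndarray
    group_ids: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[1] != len(self.group_ids):
            raise ValueError("replicate matrix shape does not match group ids")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("replicate matrix must be binary")
        if not (m.sum(axis=1) == 1).all():
            raise ValueError("each sample must belong to exactly one group")
        if (m.sum(axis=0) < 1).any():
            raise ValueError("every group needs at least one sample")
        object.__setattr__(self, "matrix", m.astype(float))
        object.__setattr__(self, "group_ids", list(self.group_ids))

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_groups(self) -> int:
        return self.matrix.shape[1]

    def group_sizes(self) -> np.ndarray:
        return self.matrix.sum(axis=0).astype(int)


class Provenance(str, Enum):
    spike_in = "spike_in"
    empirical = "empirical"
    combined = "combined"


@dataclass(frozen=True)
class ControlSet:
    """Labeled set of taxa treated as negative controls (biology-free)."""

    taxa_ids: frozenset[str]
    provenance: Provenance

    def __post_init__(self) -> None:
        if not self.taxa_ids:
            raise ValueError("control set must be non-empty")
        object.__setattr__(self, "taxa_ids", frozenset(self.taxa_ids))
        object.__setattr__(self, "provenance", Provenance(self.provenance))

    def __len__(self) -> int:
        return len(self.taxa_ids)

    def sorted_ids(self) -> list[str]:
        return sorted(self.taxa_ids)

    def restrict(self, cm: CountMatrix) -> "ControlSet":
        """Drop control taxa absent from ``cm`` (with a warning)."""
        present = self.taxa_ids & set(cm.taxa_ids)
        dropped = self.taxa_ids - present
        if dropped:
            warnings.warn(
                f"{len(dropped)} control taxa absent from matrix and dropped",
                stacklevel=2,
            )
        return ControlSet(present, self.provenance)


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path, orientation: str = "taxa_in_rows", sep: str | None = None) -> CountMatrix:
    """Read a delimited count table into a :class:`CountMatrix`.

    The first column holds taxa ids (``taxa_in_rows``, canonical) or sample
    ids (``samples_in_rows``); the header row holds the other axis.
    """
    if orientation not in ("taxa_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise CountMatrixFormatError(f"duplicate ids in {path}")
    if orientation == "samples_in_rows":
        df = df.T
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"non-numeric cells in {path}")
    return CountMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)


def write_counts(cm: CountMatrix, path, sep: str = "\t") -> None:
    cm.to_dataframe().to_csv(path, sep=sep, index_label="taxon_id")


RESERVED_METADATA_COLUMNS = ("sample_id", "replicate_group", "spiked")


def validate_metadata(md: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table (one row per sample).

    Mandatory columns ``sample_id`` and ``replicate_group``; an optional
    boolean ``spiked`` column; all other columns are named experimental
    factors.
    """
    for col in ("sample_id", "replicate_group"):
        if col not in md.columns:
            raise ValueError(f"metadata missing mandatory column {col!r}")
    if md["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    md = md.copy()
    md["sample_id"] = md["sample_id"].astype(str)
    md["replicate_group"] = md["replicate_group"].astype(str)
    if "spiked" in md.columns:
        md["spiked"] = md["spiked"].map(
            {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
        )
        if md["spiked"].isna().any():
            raise ValueError("spiked column must be boolean")
    for col in factor_names(md):
        vals = md[col].astype(str)
        if (vals.str.len() == 0).any():
            raise ValueError(f"empty level in factor {col!r}")
        md[col] = vals
    return md


def factor_names(md: pd.DataFrame) -> list[str]:
    """Names of the experimental-factor columns of a metadata table."""
    return [c for c in md.columns if c not in RESERVED_METADATA_COLUMNS]


def read_metadata(path, sep: str = "\t") -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, sep=sep))


def metadata_for(md: pd.DataFrame, sample_ids: Sequence[str]) -> pd.DataFrame:
    """Rows of ``md`` for ``sample_ids``, in that order; KeyError if missing."""
    indexed = md.set_index("sample_id")
    missing = [s for s in sample_ids if s not in indexed.index]
    if missing:
        raise KeyError(f"samples missing from metadata: {missing[:5]}")
    out = indexed.loc[list(sample_ids)].reset_index()
    return out


def read_control_list(path, provenance: Provenance | str = Provenance.empirical) -> ControlSet:
    """Read a plain-text control list: one taxon id per line, '#' comments."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.append(line)
    return ControlSet(frozenset(ids), provenance)


def write_control_list(cs: ControlSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# provenance: {cs.provenance.value}\n")
        for t in cs.sorted_ids():
            fh.write(t + "\n")


# ---------------------------------------------------------------------------
# preprocessing


def filter_by_cpm(
    cm: CountMatrix, cpm_threshold: float = 4.0, min_fraction: float = 0.15
) -> CountMatrix:
    """Keep taxa with CPM strictly above ``cpm_threshold`` in at least
    ``ceil(min_fraction * N)`` samples.

    Library sizes are the column sums of the *input* matrix, so CPM reflects
    sequencing depth rather than the filtered subset; retention depends only
    on each taxon's own counts relative to those fixed depths, which makes
    the filter idempotent.
    """
    libsize = cm.library_sizes
    if (libsize == 0).any():
        bad = [s for s, t in zip(cm.sample_ids, libsize) if t == 0]
        raise ValueError(f"samples with zero total count: {bad}")
    cpm = cm.counts / libsize * 1e6
    need = math.ceil(min_fraction * cm.n_samples)
    passing = (cpm > cpm_threshold).sum(axis=1)
    keep = passing >= need
    if not keep.any():
        raise ValueError(
            f"CPM filter removed all {cm.n_taxa} taxa "
            f"(threshold {cpm_threshold}, >= {need} samples required)"
        )
    taxa = [t for t, k in zip(cm.taxa_ids, keep) if k]
    return CountMatrix(taxa, cm.sample_ids, cm.counts[keep])


def clr_transform(cm: CountMatrix | np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform, per sample (column).

    x_ij = log(y_ij + pseudocount) - mean_i log(y_ij + pseudocount), so each
    column sums to zero. The pseudocount keeps zeros finite; 1 is the default
    (smallest integer offset) and is configurable for sensitivity checks.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    counts = cm.counts if isinstance(cm, CountMatrix) else np.asarray(cm)
    logc = np.log(counts + pseudocount)
    return logc - logc.mean(axis=0, keepdims=True)


def tss_normalize(cm: CountMatrix) -> np.ndarray:
    """Total-sum scaling: per-sample proportions (columns sum to 1)."""
    totals = cm.library_sizes
    if (totals == 0).any():
        bad = [s for s, t in zip(cm.sample_ids, totals) if t == 0]
        raise ValueError(f"cannot TSS-normalize zero-total samples: {bad}")
    return cm.counts / totals


def build_replicate_matrix(md: pd.DataFrame, sample_ids: Sequence[str]) -> ReplicateMatrix:
    """Build the binary sample-to-source membership matrix M.

    Groups are ordered by first appearance among ``sample_ids``.
    """
    rows = metadata_for(validate_metadata(md), sample_ids)
    groups: list[str] = []
    for g in rows["replicate_group"]:
        if g not in groups:
            groups.append(g)
    col = {g: i for i, g in enumerate(groups)}
    m = np.zeros((len(sample_ids), len(groups)))
    for p, g in enumerate(rows["replicate_group"]):
        m[p, col[g]] = 1.0
    return ReplicateMatrix(m, groups)
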