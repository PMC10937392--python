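"""Core in-memory containers shared by every stage of the pipeline.

All expression-like data (bulk TPM, single-cell UMI counts, metabolite
intensities) travel as an :class:`ExpressionMatrix`: a features-in-rows,
samples-in-columns pandas DataFrame plus a ``value_kind`` flag that records
the measurement scale.  Gene sets travel as a :class:`GeneSetCollection`
(the GMT model: named, ordered, duplicate-free gene lists).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("dccd")

#: Recognized measurement scales. ``tpm`` and ``counts`` are linear and
#: non-negative; ``log2_tpm1`` is log2(TPM+1), possibly median-centered
#: (may be negative); ``intensity`` is a linear metabolite abundance.
VALUE_KINDS = ("tpm", "counts", "log2_tpm1", "intensity")


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


class FormatError(ValueError):
    """Raised when an on-disk file cannot be parsed."""


@dataclass
class ExpressionMatrix:
    """Features x samples numeric matrix with identifier metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, columns are sample ids.
    value_kind
        One of :data:`VALUE_KINDS`.
    """

    values: pd.DataFrame
    value_kind: str = "tpm"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression values must be finite")
        if self.value_kind in ("tpm", "counts", "intensity") and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value at feature {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r} (kind={self.value_kind})"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, features) -> "ExpressionMatrix":
        """Restrict to the given features (order preserved, missing dropped)."""
        present = [f for f in features if f in self.values.index]
        return ExpressionMatrix(self.values.loc[present], self.value_kind)

    def to_log2(self) -> "ExpressionMatrix":
        """Return log2(x+1) of a linear-scale matrix (identity if already logged)."""
        if self.value_kind == "log2_tpm1":
            return self
        return ExpressionMatrix(np.log2(self.values + 1.0), "log2_tpm1")


@dataclass
class GeneSetCollection:
    """Named gene lists in the GMT model.

    Each set is an ordered list of unique gene identifiers.  Sets are
    non-empty unless ``allow_empty`` is set (used by signature holders that
    must record clusters with zero surviving candidates).
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    allow_empty: bool = False

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes and not self.allow_empty:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def union(self) -> list[str]:
        """De-duplicated union of all sets, in first-appearance order."""
        seen: dict[str, None] = {}
        for genes in self.sets.values():
            for g in genes:
                seen.setdefault(g)
        return list(seen)


@dataclass
class CellTable:
    """Single-cell UMI count matrix with per-cell cluster and sample labels."""

    counts: ExpressionMatrix
    cluster_label: pd.Series
    sample_of_origin: pd.Series

    def __post_init__(self) -> None:
        if self.counts.value_kind != "counts":
            raise ValidationError("CellTable counts must have value_kind='counts'")
        arr = self.counts.values.to_numpy()
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts must be integers")
        cells = self.counts.values.columns
        for name, series in (("cluster_label", self.cluster_label),
                             ("sample_of_origin", self.sample_of_origin)):
            if not series.index.equals(cells):
                # accept any order covering all cells
                if set(series.index) != set(cells):
                    raise ValidationError(f"{name} does not cover all cells")
                object.__setattr__(self, name, series.loc[cells])
        if self.cluster_label.isna().any():
            raise ValidationError("every cell needs a cluster label")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.counts.values.columns)

    def normalized(self) -> ExpressionMatrix:
        """log1p counts-per-10k normalization (the NormalizeData analog)."""
        v = self.counts.values
        depth = v.sum(axis=0)
        depth = depth.replace(0, 1.0)
        cp10k = v / depth.to_numpy()[None, :] * 1e4
        return ExpressionMatrix(np.log1p(cp10k), "log2_tpm1")


def validate_sample_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table: unique sample_id, binary events, times >= 0.

    Accepts either a ``sample_id`` column or sample ids in the index;
    returns a copy indexed by sample_id.
    """
    meta = meta.copy()
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    if meta.index.has_duplicates:
        raise ValidationError("duplicate sample_id in metadata")
    for col in ("os_event", "pfs_event"):
        if col in meta.columns:
            vals = meta[col].dropna().unique()
            if not set(vals) <= {0, 1}:
                raise ValidationError(f"{col} must be 0/1, got {sorted(vals)}")
    for col in ("os_time", "pfs_time"):
        if col in meta.columns and (meta[col].dropna() < 0).any():
            raise ValidationError(f"{col} must be non-negative")
    return meta
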