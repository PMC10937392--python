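"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices: dense TSV (features x samples) or MatrixMarket triplet
with separate row/column id files.  Gene sets: GMT.  Clinical metadata and
pathway membership: CSV with header.  All result tables are written as TSV
with >= 6 significant digits so that write-then-read round-trips at 1e-6.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .matrix import (
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    ValidationError,
    validate_sample_metadata,
)

logger = logging.getLogger("dccd")


def read_expression_tsv(path, value_kind: str = "tpm") -> ExpressionMatrix:
    """Read a dense features-x-samples TSV (first column = feature ids).

    Duplicated feature rows are collapsed: summed for counts, averaged for
    TPM/intensity (a warning is logged either way).  A malformed numeric
    cell raises :class:`FormatError` naming the offending row and column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        num = df.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise FormatError(
                    f"{path}: non-numeric value {df.loc[row, col]!r} "
                    f"at row {row!r}, column {col!r}"
                ) from None
        raise
    if num.index.has_duplicates:
        n_dup = int(num.index.duplicated().sum())
        how = "sum" if value_kind == "counts" else "mean"
        logger.warning(
            "read_expression_tsv: %d duplicated feature ids in %s collapsed by %s",
            n_dup, path.name, how,
        )
        num = num.groupby(level=0, sort=False).agg(how)
    return ExpressionMatrix(num.astype(float), value_kind)


def read_expression_mtx(mtx_path, features_path, samples_path,
                        value_kind: str = "counts") -> ExpressionMatrix:
    """Read a MatrixMarket triplet matrix plus row/column id files (one id per line)."""
    mat = scipy.io.mmread(os.fspath(mtx_path))
    features = [ln.strip() for ln in open(features_path) if ln.strip()]
    samples = [ln.strip() for ln in open(samples_path) if ln.strip()]
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    if dense.shape != (len(features), len(samples)):
        raise FormatError(
            f"matrix shape {dense.shape} does not match "
            f"{len(features)} features x {len(samples)} samples"
        )
    df = pd.DataFrame(dense, index=features, columns=samples)
    return ExpressionMatrix(df, value_kind)


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    expr.values.to_csv(path, sep="\t", float_format="%.8g", index_label="feature")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: per line ``name<TAB>description<TAB>gene...``.

    Empty gene fields are dropped; gene order is preserved; a duplicated
    set name or a line with fewer than 3 fields is a :class:`FormatError`.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno} has fewer than 3 fields")
            name, desc, *genes = fields
            if name in sets:
                raise FormatError(f"{path}: duplicate set name {name!r} at line {lineno}")
            genes = [g for g in genes if g]
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write GMT; empty sets are skipped with a warning (GMT cannot encode them)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in collection.items():
            if not genes:
                logger.warning("write_gmt: skipping empty set %r", name)
                continue
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc or "na", *genes]) + "\n")


def read_sample_metadata(path) -> pd.DataFrame:
    """Read the per-sample clinical CSV and validate it."""
    return validate_sample_metadata(pd.read_csv(path))


def read_pathway_membership(path) -> dict[str, list[str]]:
    """Read a CSV with columns (pathway, metabolite) into a membership map."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if not {"pathway", "metabolite"} <= set(cols):
        raise FormatError(f"{path}: need columns 'pathway' and 'metabolite'")
    out: dict[str, list[str]] = {}
    for pw, grp in df.groupby("pathway", sort=False):
        out[str(pw)] = [str(m) for m in grp["metabolite"]]
    return out


def write_table(obj, path) -> None:
    """Write any rectangular result table as TSV with >= 6 significant digits."""
    if not isinstance(obj, pd.DataFrame):
        obj = pd.DataFrame(obj)
    parent = Path(path).parent
    if not parent.exists():
        raise IOError(f"directory {parent} does not exist")
    obj.to_csv(path, sep="\t", float_format="%.8g",
               index=not isinstance(obj.index, pd.RangeIndex))


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
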