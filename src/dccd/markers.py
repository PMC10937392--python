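"""Marker extraction and signature-gene derivation.

Two procedures live here:

* the single-cell route — one-vs-rest Wilcoxon markers per cell cluster,
  filtered at |log2FC| > 1 and adjusted p < 0.001, capped at the top 60 per
  cluster by log2FC, and unioned into the cell-type signature matrix used
  to subtype bulk cohorts (the "911-gene" construction);
* the bulk route — per-subtype up-regulated signature genes at
  |log2FC| > 1 and adjusted p < 0.01, which become the NTP templates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CellTable, ExpressionMatrix, GeneSetCollection
from .stats import bh_adjust, log2_fold_change, rank_sum_rows

logger = logging.getLogger("dccd")

MARKER_COLUMNS = ["gene", "cluster", "log2fc", "p_value", "p_adj", "rank_in_cluster"]

#: pseudocount in fold changes, guarding zero means
EPS = 1e-9


@dataclass
class SignatureMatrix:
    """Per-cluster (or per-subtype) gene sets plus derivation provenance."""

    collection: GeneSetCollection
    provenance: dict = field(default_factory=dict)

    @property
    def total_genes(self) -> int:
        """Size of the de-duplicated union over all sets."""
        return len(self.collection.union())


def rank_markers(cells: CellTable, normalization: str = "log1p_cp10k",
                 cluster_key: str = "cluster") -> pd.DataFrame:
    """One-vs-rest Wilcoxon markers for every cell cluster.

    Counts are normalized to log1p counts-per-10k; the rank-sum test runs
    on the normalized values while fold changes compare de-logged (cp10k)
    cluster means with a 1e-9 pseudocount.  BH adjustment is applied
    jointly across all gene x cluster tests.  Clusters with fewer than 3
    cells are excluded with a warning.
    """
    if normalization != "log1p_cp10k":
        raise ValueError(f"unknown normalization {normalization!r}")
    norm = cells.normalized().values  # genes x cells, log1p cp10k
    delogged = np.expm1(norm.to_numpy())
    labels = cells.cluster_label
    clusters = [c for c in pd.unique(labels)]
    keep = []
    for c in clusters:
        n_c = int((labels == c).sum())
        if n_c < 3:
            logger.warning("rank_markers: cluster %r has %d < 3 cells; excluded", c, n_c)
        else:
            keep.append(c)
    if len(keep) < 2:
        raise ValueError("need at least 2 clusters with >= 3 cells")

    vals = norm.to_numpy()
    frames = []
    for c in keep:
        mask = (labels == c).to_numpy()
        p = rank_sum_rows(vals, mask)
        mean_in = delogged[:, mask].mean(axis=1)
        mean_rest = delogged[:, ~mask].mean(axis=1)
        lfc = log2_fold_change(mean_in, mean_rest, EPS)
        const = np.ptp(vals, axis=1) == 0
        lfc[const] = 0.0
        p[const] = 1.0
        frames.append(pd.DataFrame({
            "gene": norm.index, "cluster": c, "log2fc": lfc, "p_value": p,
        }))
    out = pd.concat(frames, ignore_index=True)
    out["p_adj"] = bh_adjust(out["p_value"].to_numpy())
    out = _assign_ranks(out)
    logger.info("rank_markers: %d clusters x %d genes -> %d tests",
                len(keep), norm.shape[0], len(out))
    return out[MARKER_COLUMNS]


def _assign_ranks(markers: pd.DataFrame) -> pd.DataFrame:
    """Within-cluster rank by log2fc desc, ties by smaller p then gene id."""
    markers = markers.sort_values(
        ["cluster", "log2fc", "p_value", "gene"],
        ascending=[True, False, True, True], kind="mergesort",
    ).reset_index(drop=True)
    markers["rank_in_cluster"] = markers.groupby("cluster", sort=False).cumcount() + 1
    return markers


def build_signature_matrix(markers: pd.DataFrame, log2fc_cutoff: float = 1.0,
                           padj_cutoff: float = 1e-3, top_n: int = 60) -> SignatureMatrix:
    """Cap each cluster at its top-``top_n`` up-regulated candidates.

    Candidates must pass both cutoffs with log2fc > 0; within a cluster
    they are sorted by log2fc descending (ties by smaller p, then gene id)
    and truncated.  The union across clusters is de-duplicated for the
    signature matrix's gene universe while per-cluster sets keep their own
    members.  A cluster with zero candidates keeps an empty set.
    """
    if markers.empty:
        raise ValueError("marker table is empty")
    cand = markers[(markers["log2fc"].abs() > log2fc_cutoff)
                   & (markers["log2fc"] > 0)
                   & (markers["p_adj"] < padj_cutoff)]
    sets: dict[str, list[str]] = {}
    for c in pd.unique(markers["cluster"]):
        sub = cand[cand["cluster"] == c].sort_values(
            ["log2fc", "p_value", "gene"], ascending=[False, True, True],
            kind="mergesort")
        genes = sub["gene"].head(top_n).tolist()
        if not genes:
            logger.warning("build_signature_matrix: cluster %r has no candidates", c)
        sets[str(c)] = genes
    coll = GeneSetCollection(sets, allow_empty=True)
    sig = SignatureMatrix(coll, provenance={
        "log2fc_cutoff": log2fc_cutoff, "padj_cutoff": padj_cutoff, "top_n": top_n,
    })
    logger.info("build_signature_matrix: %d clusters, union of %d genes",
                len(sets), sig.total_genes)
    return sig


def derive_subtype_signatures(bulk: ExpressionMatrix, labels: pd.Series,
                              log2fc_cutoff: float = 1.0,
                              padj_cutoff: float = 0.01) -> SignatureMatrix:
    """Per-subtype up-regulated signature genes from a labeled bulk cohort.

    One-vs-rest Wilcoxon on log2(TPM+1) with BH adjustment per contrast;
    genes passing log2fc > cutoff and adjusted p < cutoff form one set per
    subtype (sorted by log2fc descending).
    """
    labels = labels.loc[bulk.sample_ids]
    counts = labels.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"subtypes with < 2 samples: {list(small.index)}")
    logx = bulk.to_log2().values.to_numpy()
    tpm = bulk.values.to_numpy() if bulk.value_kind != "log2_tpm1" \
        else 2.0 ** bulk.values.to_numpy() - 1.0
    sets: dict[str, list[str]] = {}
    for subtype in sorted(counts.index):
        mask = (labels == subtype).to_numpy()
        p = rank_sum_rows(logx, mask)
        p_adj = bh_adjust(p)
        lfc = log2_fold_change(tpm[:, mask].mean(axis=1),
                               tpm[:, ~mask].mean(axis=1), EPS)
        ok = (lfc > log2fc_cutoff) & (p_adj < padj_cutoff)
        order = np.argsort(-lfc[ok], kind="stable")
        sets[subtype] = list(np.asarray(bulk.feature_ids)[ok][order])
        logger.info("derive_subtype_signatures: %s -> %d genes",
                    subtype, int(ok.sum()))
    return SignatureMatrix(
        GeneSetCollection(sets, allow_empty=True),
        provenance={"log2fc_cutoff": log2fc_cutoff, "padj_cutoff": padj_cutoff},
    )
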