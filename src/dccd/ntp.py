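"""Nearest-template prediction (NTP) of molecular subtype.

Each subtype is encoded as a binary template over the union of all subtype
signature genes; a sample is assigned to the template with the smallest
correlation distance (1 - Pearson r).  Significance comes from a
gene-label permutation null: the sample's adjusted values are shuffled
over the gene universe and re-classified, and the p-value is the smoothed
fraction of permutations whose nearest-template distance is at most the
observed one.  BH FDR is computed across samples.

Expression is first RLE-style adjusted: log2(TPM+1) then per-gene median
centering across the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, GeneSetCollection
from .stats import bh_adjust

logger = logging.getLogger("dccd")


@dataclass
class TemplateSet:
    """Binary one-vs-all subtype templates over a shared gene universe."""

    gene_universe: list[str]
    templates: pd.DataFrame  # subtypes x genes, 0/1

    @classmethod
    def from_signatures(cls, signatures: GeneSetCollection) -> "TemplateSet":
        universe = signatures.union()
        if not universe:
            raise ValueError("signatures are empty")
        T = pd.DataFrame(0.0, index=list(signatures), columns=universe)
        for name, genes in signatures.items():
            if not genes:
                raise ValueError(f"template {name!r} has no genes")
            T.loc[name, genes] = 1.0
        return cls(universe, T)


def adjust_expression(expr: ExpressionMatrix) -> ExpressionMatrix:
    """RLE-style adjustment: log2(x+1) if linear, then per-gene median centering.

    Idempotent; requires a cohort (>= 2 samples) since a single sample
    cannot be median-centered meaningfully.
    """
    if expr.shape[1] < 2:
        raise ValueError("cannot median-center a single-sample matrix; "
                         "provide the full cohort")
    logx = expr.to_log2().values
    centered = logx.sub(logx.median(axis=1), axis=0)
    return ExpressionMatrix(centered, "log2_tpm1")


def _corr_to_templates(x: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector x with each row of T (returns K floats)."""
    xc = x - x.mean()
    Tc = T - T.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum()) * np.sqrt((Tc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Tc @ xc) / denom


def ntp_classify(expr_adj: ExpressionMatrix, templates: TemplateSet,
                 n_perm: int = 1000, seed: int = 42,
                 exhaustive: bool = False) -> pd.DataFrame:
    """Assign each sample to its nearest template with a permutation p-value.

    The null re-classifies each permuted sample (minimum distance over all
    templates), so p-values are calibrated under pure noise.  With
    ``exhaustive``, all G! gene permutations are enumerated instead of
    sampling (only sensible for tiny universes).
    """
    present = [g for g in templates.gene_universe if g in set(expr_adj.feature_ids)]
    frac = len(present) / len(templates.gene_universe)
    if frac < 0.5:
        raise ValueError(f"only {frac:.0%} of the template gene universe is "
                         "present in the matrix (need >= 50%)")
    T_full = templates.templates
    T = T_full[present]
    for name in T.index:
        kept = T.loc[name].sum()
        total = T_full.loc[name].sum()
        if kept < 0.5 * total:
            raise ValueError(f"template {name!r} lost more than 50% of its genes")
    subtype_names = sorted(T.index)  # lexicographic tie order
    Tm = T.loc[subtype_names].to_numpy(float)
    X = expr_adj.values.reindex(present).to_numpy(float)
    n_genes, n_samples = X.shape

    rng = np.random.default_rng(seed)
    if exhaustive:
        if n_genes > 8:
            raise ValueError("exhaustive permutation only for tiny universes")
        perms = np.array(list(iter_permutations(range(n_genes))))
    else:
        perms = np.array([rng.permutation(n_genes) for _ in range(n_perm)])

    rows = []
    for j, sid in enumerate(expr_adj.sample_ids):
        x = X[:, j]
        if np.ptp(x) == 0:
            logger.warning("ntp_classify: sample %r has zero variance over the "
                           "gene universe; unclassifiable", sid)
            rows.append({"sample_id": sid, "subtype": None, "source": "ntp",
                         "distance": np.nan, "p_value": np.nan, "fdr": np.nan,
                         "tie": False, "unclassifiable": True})
            continue
        d = 1.0 - _corr_to_templates(x, Tm)
        d = np.where(np.isnan(d), np.inf, d)
        d_min = d.min()
        winners = np.where(np.isclose(d, d_min, rtol=0, atol=1e-12))[0]
        tie = len(winners) > 1
        win = winners.min()  # lexicographic order of subtype_names
        # permutation null: nearest-template distance of each permuted sample
        Xp = x[perms]  # n_perm x genes
        corr_p = _perm_corr(Xp, Tm)
        d_perm = 1.0 - corr_p.max(axis=1)
        if exhaustive:
            p = float((d_perm <= d_min + 1e-12).sum()) / len(perms)
        else:
            p = (1.0 + float((d_perm <= d_min + 1e-12).sum())) / (len(perms) + 1.0)
        rows.append({"sample_id": sid, "subtype": subtype_names[win],
                     "source": "ntp", "distance": float(d_min), "p_value": p,
                     "tie": tie, "unclassifiable": False})
    out = pd.DataFrame(rows)
    ok = ~out["unclassifiable"]
    out.loc[ok, "fdr"] = bh_adjust(out.loc[ok, "p_value"].to_numpy())
    return out[["sample_id", "subtype", "source", "distance", "p_value", "fdr",
                "tie", "unclassifiable"]]


def _perm_corr(Xp: np.ndarray, Tm: np.ndarray) -> np.ndarray:
    """Correlation of each permuted sample (rows of Xp) with each template."""
    G = Xp.shape[1]
    xc = Xp - Xp.mean(axis=1, keepdims=True)
    Tc = Tm - Tm.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum(axis=1))[:, None] * \
        np.sqrt((Tc ** 2).sum(axis=1))[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        return (xc @ Tc.T) / denom
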