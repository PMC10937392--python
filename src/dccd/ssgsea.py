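"""Single-sample GSEA (ssGSEA) scoring, implemented from first principles.

For one sample, genes are ranked by expression (rank 1 = highest); walking
the ranked list, the enrichment score is the summed difference between the
weighted in-set cumulative distribution and the unweighted out-of-set one:

    ES = sum_k [ P_in^w(k) - P_out(k) ]
    P_in^w(k) = sum_{i in S, pos(i) <= k} r_i^alpha / sum_{i in S} r_i^alpha
    P_out(k)  = #{i not in S, pos(i) <= k} / (N - |S|)

with r_i = N - rank_i + 1 (average ranks under ties) and alpha = 0.25 by
default.  When ``normalize`` is on, the whole score matrix is divided by
its global (max - min), the GSVA-style normalization.

Scores are rank-based, hence invariant to any strictly monotone transform
of a sample's expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .matrix import ExpressionMatrix, GeneSetCollection
from .stats import bh_adjust

logger = logging.getLogger("dccd")


@dataclass
class SsgseaScores:
    """Sets x samples enrichment scores."""

    scores: pd.DataFrame
    alpha: float
    normalized: bool


def _effective_sets(expr: ExpressionMatrix, sets: GeneSetCollection) -> dict[str, list[str]]:
    present = set(expr.feature_ids)
    eff: dict[str, list[str]] = {}
    for name, genes in sets.items():
        kept = [g for g in genes if g in present]
        dropped = len(genes) - len(kept)
        if dropped:
            logger.warning("ssgsea: set %r: %d genes absent from matrix", name, dropped)
        if len(kept) < 2:
            raise ValueError(f"gene set {name!r} has < 2 genes present in the matrix")
        if len(kept) >= expr.shape[0]:
            raise ValueError(f"gene set {name!r} covers the whole matrix")
        eff[name] = kept
    return eff


def ssgsea(expr: ExpressionMatrix, sets: GeneSetCollection,
           alpha: float = 0.25, normalize: bool = True) -> SsgseaScores:
    """Per-sample enrichment score for every gene set.

    Ties get average ranks; the walk order is deterministic (expression
    descending, then gene id), so results are platform-independent.
    """
    eff = _effective_sets(expr, sets)
    # fix row order to gene-id lexicographic so the stable sort breaks ties by id
    df = expr.values.sort_index(kind="mergesort")
    genes = df.index
    X = df.to_numpy(float)
    n_genes, n_samples = X.shape
    set_names = list(eff)
    member = np.zeros((len(set_names), n_genes), dtype=bool)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for si, name in enumerate(set_names):
        member[si, [gene_pos[g] for g in eff[name]]] = True
    set_sizes = member.sum(axis=1)

    out = np.empty((len(set_names), n_samples))
    for j in range(n_samples):
        col = X[:, j]
        # r_i = N - rank_desc_i + 1 == ascending average rank
        r = scipy.stats.rankdata(col)
        order = np.argsort(-col, kind="stable")
        w = r[order] ** alpha
        m_ord = member[:, order]  # sets x genes, walk order
        in_w = m_ord * w[None, :]
        in_cum = np.cumsum(in_w, axis=1)
        in_tot = in_cum[:, -1][:, None]
        p_in = in_cum / in_tot
        out_cum = np.cumsum(~m_ord, axis=1)
        p_out = out_cum / (n_genes - set_sizes)[:, None]
        out[:, j] = (p_in - p_out).sum(axis=1)

    scores = pd.DataFrame(out, index=set_names, columns=df.columns)
    if normalize:
        rng_ = out.max() - out.min()
        if rng_ > 0:
            scores = scores / rng_
    return SsgseaScores(scores, alpha=alpha, normalized=normalize)


def score_contrast(scores: SsgseaScores, groups: pd.Series,
                   contrast: tuple[str, str] = ("A", "rest")) -> pd.DataFrame:
    """Two-group comparison of score rows: pooled-variance t statistic + BH.

    ``contrast[0]`` names the group of interest; every other sample is the
    reference.  Positive t means higher scores in the named group.  Sets
    with zero variance on both sides report t = 0, p = 1 and are flagged.
    """
    groups = groups.loc[scores.scores.columns]
    mask = (groups == contrast[0]).to_numpy()
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples on each side of the contrast")
    a = scores.scores.to_numpy()[:, mask]
    b = scores.scores.to_numpy()[:, ~mask]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = np.zeros(len(ma))
    p = np.ones(len(ma))
    degenerate = se == 0
    ok = ~degenerate
    t[ok] = (ma[ok] - mb[ok]) / se[ok]
    p[ok] = 2 * scipy.stats.t.sf(np.abs(t[ok]), df=n1 + n2 - 2)
    return pd.DataFrame({
        "set": scores.scores.index,
        "t_statistic": t,
        "p": p,
        "p_adj": bh_adjust(p),
        "degenerate": degenerate,
    })
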