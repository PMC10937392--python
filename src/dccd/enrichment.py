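"""Cross-cutting enrichment statistics.

* Odds-ratio grid: one-sided Fisher exact tests for whether a cell
  subcluster preferentially distributes in a molecular subtype
  (enriched: OR > 1.5, adjusted p < 0.05; depleted: OR < 0.5).
* Two-group differential abundance (Wilcoxon + log2FC + BH) shared by
  proteins, metabolites and TPM-like features.
* The metabolomic DA score: (n_up - n_down) / n_measured per pathway.
* Pearson score-score correlation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from .matrix import CellTable, ExpressionMatrix
from .stats import bh_adjust, log2_fold_change, pearson, rank_sum_rows

logger = logging.getLogger("dccd")

score_correlation = pearson


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Equals the hypergeometric upper tail P(X >= a) with population a+b+c+d,
    a+c successes and a+b draws.
    """
    n = a + b + c + d
    return float(scipy.stats.hypergeom.sf(a - 1, n, a + c, a + b))


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio with a Haldane +0.5 correction iff any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def or_grid(cells: CellTable, subtype_of_sample: dict[str, str] | pd.Series,
            or_hi: float = 1.5, or_lo: float = 0.5,
            padj_cutoff: float = 0.05) -> pd.DataFrame:
    """Subcluster x subtype preference grid.

    For each (cluster, subtype) pair the 2x2 table counts cells
    in/out of the cluster crossed with in/out of the subtype; one-sided
    Fisher p-values are BH-adjusted across the whole grid.
    """
    sub = pd.Series(subtype_of_sample)
    samples = cells.sample_of_origin
    missing = set(samples.unique()) - set(sub.index)
    if missing:
        raise ValueError(f"samples without a subtype: {sorted(missing)}")
    cell_subtype = samples.map(sub)
    cl = cells.cluster_label
    clusters = sorted(cl.unique())
    subtypes = sorted(cell_subtype.unique())
    total = len(cl)
    rows = []
    for clu in clusters:
        in_cl = cl == clu
        n_cl = int(in_cl.sum())
        if n_cl == 0:
            logger.warning("or_grid: empty cluster %r omitted", clu)
            continue
        for st in subtypes:
            in_st = cell_subtype == st
            n_st = int(in_st.sum())
            if n_st == 0:
                logger.warning("or_grid: empty subtype %r omitted", st)
                continue
            a = int((in_cl & in_st).sum())
            b = n_cl - a
            c = n_st - a
            d = total - a - b - c
            orr = odds_ratio(a, b, c, d)
            # one-sided p in the direction the odds ratio points: the
            # upper (enrichment) tail when OR >= 1, else the lower tail
            # (the upper tail of the swapped table), so both enrichment
            # and depletion calls are testable
            if orr >= 1:
                p = fisher_one_sided(a, b, c, d)
            else:
                p = fisher_one_sided(b, a, d, c)
            rows.append({"cluster": clu, "subtype": st,
                         "a": a, "b": b, "c": c, "d": d,
                         "odds_ratio": orr, "p_value": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_value"].to_numpy())
    sig = out["p_adj"] < padj_cutoff
    out["call"] = np.select(
        [sig & (out["odds_ratio"] > or_hi), sig & (out["odds_ratio"] < or_lo)],
        ["enriched", "depleted"], default="neutral")
    return out


def diff_abundance(expr: ExpressionMatrix, groups: pd.Series,
                   log2fc_cutoff: float = 1.0,
                   padj_cutoff: float = 0.01) -> pd.DataFrame:
    """Two-group Wilcoxon differential abundance with printed-cutoff calls.

    log2FC compares group means: TPM-like data use a +1 pseudocount;
    metabolite intensities a machine-safe 1e-9.  Counts are converted to
    CPM first.  Directions: up / down when both |log2FC| and BH-adjusted p
    pass the cutoffs, else ns.  The first group in sorted label order is
    the reference (B); the other is A, so positive log2FC means higher in A.
    """
    groups = groups.loc[expr.sample_ids]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    counts = groups.value_counts()
    if (counts < 3).any():
        raise ValueError("need >= 3 samples per group")
    ref, alt = levels[0], levels[1]
    # convention: tumor vs normal — if one label is a control-like name, use it as reference
    for ctl in ("normal", "NAT", "nat", "control"):
        if ctl in levels:
            ref = ctl
            alt = [l for l in levels if l != ctl][0]
            break
    vals = expr.values.to_numpy(float)
    if expr.value_kind == "counts":
        vals = vals / vals.sum(axis=0, keepdims=True) * 1e6
    mask_a = (groups == alt).to_numpy()
    p = rank_sum_rows(vals, mask_a)
    pseudo = 1.0 if expr.value_kind in ("tpm", "counts") else 1e-9
    lfc = log2_fold_change(vals[:, mask_a].mean(axis=1),
                           vals[:, ~mask_a].mean(axis=1), pseudo)
    const = np.ptp(vals, axis=1) == 0
    p[const] = 1.0
    lfc[const] = 0.0
    p_adj = bh_adjust(p)
    direction = np.select(
        [(lfc > log2fc_cutoff) & (p_adj < padj_cutoff),
         (lfc < -log2fc_cutoff) & (p_adj < padj_cutoff)],
        ["up", "down"], default="ns")
    return pd.DataFrame({
        "feature": expr.feature_ids, "log2fc": lfc, "p_value": p,
        "p_adj": p_adj, "direction": direction,
        "group_a": alt, "group_b": ref,
    })


def da_scores(diff: pd.DataFrame, pathways: dict[str, list[str]]) -> pd.DataFrame:
    """Differential-abundance score per metabolite pathway.

    score = (n_up - n_down) / n_measured over the pathway's members present
    in the differential table; pathways with no measured member are
    omitted with a warning.
    """
    direction = diff.set_index("feature")["direction"]
    rows = []
    for pw, members in pathways.items():
        present = [m for m in members if m in direction.index]
        if not present:
            logger.warning("da_scores: pathway %r has no measured metabolites; omitted", pw)
            continue
        d = direction.loc[present]
        n_up = int((d == "up").sum())
        n_down = int((d == "down").sum())
        rows.append({"pathway": pw, "n_up": n_up, "n_down": n_down,
                     "n_measured": len(present),
                     "score": (n_up - n_down) / len(present)})
    return pd.DataFrame(rows, columns=["pathway", "n_up", "n_down",
                                       "n_measured", "score"])
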