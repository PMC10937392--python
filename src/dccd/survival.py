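"""Kaplan-Meier estimation and log-rank comparisons between subtype groups.

Thin, validated layer over lifelines: product-limit curves per group, the
global (g-1)-df log-rank chi-square, and BH-adjusted pairwise tests that
run only when the global p is below 0.05 (the printed procedure; a flag
forces all pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, pairwise_logrank_test

from .matrix import ValidationError
from .stats import bh_adjust

SURVIVAL_COLUMNS = ("sample_id", "time", "event", "group")


@dataclass
class KmCurve:
    """Product-limit survival curve for one group."""

    group: str
    times: np.ndarray      # distinct observed times, increasing
    survival: np.ndarray   # S(t) just after each time, starts from S=1 at t=0
    at_risk: np.ndarray    # risk-set size just before each time


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    records = pd.DataFrame(records)
    missing = set(SURVIVAL_COLUMNS) - set(records.columns)
    if missing:
        raise ValidationError(f"missing survival columns: {sorted(missing)}")
    if (records["time"] <= 0).any():
        raise ValidationError("times must be positive")
    if not set(records["event"].unique()) <= {0, 1}:
        raise ValidationError("event must be 0/1")
    return records


def km_fit(records: pd.DataFrame) -> dict[str, KmCurve]:
    """Kaplan-Meier product-limit estimate per group."""
    records = validate_records(records)
    curves: dict[str, KmCurve] = {}
    for grp, sub in records.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        sf = kmf.survival_function_
        tbl = kmf.event_table
        times = sf.index.to_numpy(float)
        curves[str(grp)] = KmCurve(
            group=str(grp),
            times=times,
            survival=sf.iloc[:, 0].to_numpy(float),
            at_risk=tbl["at_risk"].reindex(sf.index).to_numpy(float),
        )
    return curves


def logrank(records: pd.DataFrame, pairwise: bool = True,
            padj: str = "BH", alpha: float = 0.05,
            force_pairwise: bool = False):
    """Global log-rank test across groups, plus gated pairwise comparisons.

    Returns ``(chi2, p, pairwise_table)``; the pairwise table is None
    unless the global p < alpha (or ``force_pairwise``).  Pairwise p-values
    are BH-adjusted.
    """
    if padj != "BH":
        raise ValueError("only BH adjustment is supported")
    records = validate_records(records)
    groups = records["group"].unique()
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if records["event"].sum() == 0:
        raise ValueError("need >= 1 event")
    res = multivariate_logrank_test(records["time"], records["group"],
                                    records["event"])
    chi2, p = float(res.test_statistic), float(res.p_value)
    table = None
    if pairwise and (p < alpha or force_pairwise):
        pw = pairwise_logrank_test(records["time"], records["group"],
                                   records["event"])
        summary = pw.summary.reset_index()
        table = pd.DataFrame({
            "group_a": summary.iloc[:, 0].astype(str),
            "group_b": summary.iloc[:, 1].astype(str),
            "chi2": summary["test_statistic"].to_numpy(float),
            "p_value": summary["p"].to_numpy(float),
        })
        table["p_adj"] = bh_adjust(table["p_value"].to_numpy())
    return chi2, p, table
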