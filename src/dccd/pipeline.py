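"""End-to-end synthetic pipeline driver.

Binds every stage in dependency order on generated cohorts with planted
truth: simulate single cells -> extract the cell-type signature matrix;
simulate a bulk cohort -> consensus subtyping (k pinned at 4) -> name the
clusters -> derive per-subtype signature genes; NTP-classify a held-out
cohort; DCCD-score samples and cells; metabolite DA and survival reports.
A stage failure aborts its dependents; independent branches continue.
Artifacts are plain files under ``config.output_dir``; the resolved config
and seed are written beside them.
"""

from __future__ import annotations

import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import io as dio
from .config import RunConfig
from .consensus import assign_subtype_names, consensus_cluster
from .enrichment import da_scores, diff_abundance, or_grid
from .markers import build_signature_matrix, derive_subtype_signatures, rank_markers
from .ntp import TemplateSet, adjust_expression, ntp_classify
from .scoring import dccd_score, dccd_score_cells, dccd_trajectory
from .stats import pearson
from .survival import km_fit, logrank
from .synthetic import (
    default_bulk_signatures,
    simulate_bulk_cohort,
    simulate_dccd_cells,
    simulate_metabolome,
    simulate_sc_counts,
)

logger = logging.getLogger("dccd")


@dataclass
class PipelineReport:
    """Per-stage outcomes plus recovery metrics against the planted truth."""

    config: RunConfig
    stages: dict[str, dict] = field(default_factory=dict)
    metrics: dict[str, float] = field(default_factory=dict)

    def record(self, name: str, status: str, reason: str = "",
               **outputs) -> None:
        self.stages[name] = {"status": status, "reason": reason,
                             "outputs": {k: str(v) for k, v in outputs.items()}}

    def ok(self, name: str) -> bool:
        return self.stages.get(name, {}).get("status") == "ok"

    def to_json(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        payload = {"seed": self.config.seed, "stages": self.stages,
                   "metrics": self.metrics}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def marker_recovery(markers: pd.DataFrame, truth,
                    log2fc_cutoff: float = 1.0,
                    padj_cutoff: float = 1e-3) -> dict[str, float]:
    """Precision/recall of planted markers among called candidates, and the
    AUROC of retrieving planted markers from the per-cluster ranking."""
    planted = {(c, g) for c, gs in truth.planted_markers.items() for g in gs}
    called = {(r.cluster, r.gene) for r in markers.itertuples()
              if r.log2fc > log2fc_cutoff and r.p_adj < padj_cutoff}
    tp = len(planted & called)
    precision = tp / len(called) if called else 0.0
    recall = tp / len(planted) if planted else 0.0
    # AUROC: rank all gene x cluster pairs by -log2fc; planted = positives
    is_pos = np.array([(r.cluster, r.gene) in planted for r in markers.itertuples()])
    score = markers["log2fc"].to_numpy()
    order = np.argsort(-score, kind="stable")
    ranks = np.empty(len(order)); ranks[order] = np.arange(1, len(order) + 1)
    n_pos, n_neg = is_pos.sum(), (~is_pos).sum()
    auroc = 1.0 - (ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return {"marker_precision": precision, "marker_recall": recall,
            "marker_auroc": float(auroc)}


def evaluate_against_truth(outputs: dict, truth_map: dict) -> dict[str, float]:
    """Recovery metrics for whichever stage outputs are present.

    ARI for consensus labels, accuracy for NTP, Pearson r for DCCD vs the
    planted mixing fraction, precision/recall for DA directions.
    """
    metrics: dict[str, float] = {}
    if "consensus_labels" in outputs:
        lab = outputs["consensus_labels"]
        truth = truth_map["bulk"].bulk_subtype_labels
        if not lab.index.equals(truth.index) and set(lab.index) != set(truth.index):
            raise ValueError("consensus labels and truth sample ids differ")
        metrics["consensus_ari"] = float(
            adjusted_rand_score(truth.loc[lab.index], lab))
    if "ntp_assignments" in outputs:
        ntp = outputs["ntp_assignments"].set_index("sample_id")["subtype"]
        truth = truth_map["holdout"].bulk_subtype_labels
        metrics["ntp_accuracy"] = float((ntp.loc[truth.index] == truth).mean())
    if "dccd_results" in outputs:
        res = outputs["dccd_results"].set_index("entity_id")
        mix = truth_map["gradient"].dccd_mixing_fraction
        r, _ = pearson(res.loc[mix.index, "dccd_score"], mix)
        metrics["dccd_mixing_r"] = r
    if "da_table" in outputs:
        da = outputs["da_table"].set_index("pathway")["score"]
        expected = truth_map["metabolome"].expected_da_score
        errs = [abs(da.get(pw, 0.0) - v) for pw, v in expected.items()]
        metrics["da_score_max_abs_error"] = float(max(errs)) if errs else 0.0
    return metrics


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Run every stage on synthetic cohorts; returns the stage report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "resolved_config.cfg")
    report = PipelineReport(config=config)
    seed = config.seed
    truth_map: dict = {}
    outputs: dict = {}

    # --- single-cell branch: markers -> signature matrix -----------------
    try:
        cells, sc_truth = simulate_sc_counts(seed=seed)
        truth_map["sc"] = sc_truth
        markers = rank_markers(cells)
        sig = build_signature_matrix(
            markers, config.marker_log2fc_cutoff,
            config.marker_padj_cutoff, config.marker_top_n)
        dio.write_table(markers, out / "markers.tsv")
        dio.write_gmt(sig.collection, out / "cell_signatures.gmt")
        report.metrics.update(marker_recovery(
            markers, sc_truth, config.marker_log2fc_cutoff,
            config.marker_padj_cutoff))
        report.record("markers", "ok", markers=out / "markers.tsv",
                      signatures=out / "cell_signatures.gmt")
    except Exception as exc:  # noqa: BLE001 - stage isolation
        report.record("markers", "failed", reason=_why(exc))

    # --- bulk branch: consensus subtyping -> subtype signatures ----------
    try:
        signatures = default_bulk_signatures()
        bulk, meta, bulk_truth = simulate_bulk_cohort(
            signatures=signatures, seed=seed)
        truth_map["bulk"] = bulk_truth
        cons = consensus_cluster(
            bulk, signatures.union(), k_range=config.k_range,
            n_resamples=config.n_resamples,
            subsample_fraction=config.subsample_fraction, seed=seed)
        named = assign_subtype_names(cons, bulk, signatures, k=config.pinned_k)
        labels = named.set_index("sample_id")["subtype"]
        outputs["consensus_labels"] = labels
        dio.write_table(named, out / "consensus_assignments.tsv")
        dio.write_table(
            pd.DataFrame({"k": list(cons.cdf_area),
                          "cdf_area": list(cons.cdf_area.values()),
                          "delta_area": [cons.delta_area[k] for k in cons.cdf_area]}),
            out / "cdf_area.tsv")
        report.record("consensus", "ok",
                      assignments=out / "consensus_assignments.tsv")
    except Exception as exc:
        report.record("consensus", "failed", reason=_why(exc))
        bulk = meta = None

    try:
        if bulk is None:
            raise RuntimeError("consensus stage failed")
        subsig = derive_subtype_signatures(
            bulk, labels, config.subtype_log2fc_cutoff,
            config.subtype_padj_cutoff)
        dio.write_gmt(subsig.collection, out / "subtype_signatures.gmt")
        report.record("subtype_signatures", "ok",
                      gmt=out / "subtype_signatures.gmt")
    except Exception as exc:
        report.record("subtype_signatures", "failed", reason=_why(exc))
        subsig = None

    # --- held-out cohort: NTP classification -----------------------------
    try:
        if subsig is None:
            raise RuntimeError("subtype signature stage failed")
        holdout, _, holdout_truth = simulate_bulk_cohort(
            n_samples=100, signatures=default_bulk_signatures(), seed=seed + 1)
        truth_map["holdout"] = holdout_truth
        templates = TemplateSet.from_signatures(subsig.collection)
        assigned = ntp_classify(adjust_expression(holdout), templates,
                                n_perm=config.ntp_nperm, seed=config.ntp_seed)
        outputs["ntp_assignments"] = assigned
        dio.write_table(assigned, out / "ntp_assignments.tsv")
        report.record("ntp", "ok", assignments=out / "ntp_assignments.tsv")
    except Exception as exc:
        report.record("ntp", "failed", reason=_why(exc))

    # --- DCCD branch ------------------------------------------------------
    try:
        signatures = default_bulk_signatures()
        grad, _, grad_truth = simulate_bulk_cohort(
            n_samples=150, signatures=signatures, dccd_gradient=True,
            seed=seed + 2)
        truth_map["gradient"] = grad_truth
        res = dccd_score(grad, signatures["IM2"], signatures["IM4"],
                         alpha=config.ssgsea_alpha)
        outputs["dccd_results"] = res
        dio.write_table(res, out / "dccd_scores.tsv")
        traj = dccd_trajectory(res, grad.to_log2(),
                               signatures["IM4"][:10], window=11)
        dio.write_table(traj, out / "dccd_trajectory.tsv")
        mix_cells, mix_truth = simulate_dccd_cells(seed=seed + 3)
        cell_res, frac = dccd_score_cells(
            mix_cells, list(mix_truth.planted_markers["IM2-arch"]),
            list(mix_truth.planted_markers["IM4-arch"]))
        dio.write_table(frac.to_frame(), out / "im4_like_fraction.tsv")
        r, _ = pearson(frac.loc[mix_truth.dccd_mixing_fraction.index],
                       mix_truth.dccd_mixing_fraction)
        report.metrics["cell_fraction_vs_planted_r"] = r
        # OR grid: subtype of each mixture sample = dominant archetype
        subtype = mix_truth.dccd_mixing_fraction.map(
            lambda f: "IM4" if f >= 0.5 else "IM2")
        grid = or_grid(mix_cells, subtype, padj_cutoff=config.or_padj_cutoff)
        dio.write_table(grid, out / "or_grid.tsv")
        report.record("dccd", "ok", scores=out / "dccd_scores.tsv",
                      or_grid=out / "or_grid.tsv")
    except Exception as exc:
        report.record("dccd", "failed", reason=_why(exc))

    # --- metabolome branch ------------------------------------------------
    try:
        pathways = {f"pw{k}": [f"m{k}_{i}" for i in range(10)] for k in range(4)}
        shifts = {"pw0": (4, 1, 3.0), "pw1": (0, 6, 3.0)}
        metab, metab_truth = simulate_metabolome(
            pathways=pathways, shifts=shifts, seed=seed + 4)
        truth_map["metabolome"] = metab_truth
        diff = diff_abundance(metab, metab_truth.group_labels,
                              config.diff_log2fc_cutoff, config.diff_padj_cutoff)
        da = da_scores(diff, pathways)
        outputs["da_table"] = da
        dio.write_table(diff, out / "metabolite_diff.tsv")
        dio.write_table(da, out / "da_scores.tsv")
        report.record("metabolome", "ok", da=out / "da_scores.tsv")
    except Exception as exc:
        report.record("metabolome", "failed", reason=_why(exc))

    # --- survival branch --------------------------------------------------
    try:
        if meta is None:
            raise RuntimeError("bulk cohort unavailable")
        records = pd.DataFrame({
            "sample_id": meta.index,
            "time": meta["os_time"].to_numpy(),
            "event": meta["os_event"].to_numpy(),
            "group": truth_map["bulk"].bulk_subtype_labels.loc[meta.index].to_numpy(),
        })
        records = records[records["time"] > 0]
        km_fit(records)
        chi2, p, pairs = logrank(records)
        report.metrics["logrank_chi2"] = chi2
        report.metrics["logrank_p"] = p
        summary = pd.DataFrame({"chi2": [chi2], "p": [p]})
        dio.write_table(summary, out / "logrank_global.tsv")
        if pairs is not None:
            dio.write_table(pairs, out / "logrank_pairwise.tsv")
        report.record("survival", "ok", summary=out / "logrank_global.tsv")
    except Exception as exc:
        report.record("survival", "failed", reason=_why(exc))

    report.metrics.update(evaluate_against_truth(outputs, truth_map))
    report.to_json(out / "report.json")
    return report


def _why(exc: Exception) -> str:
    logger.error("stage failed: %s", exc)
    logger.debug("%s", traceback.format_exc())
    return f"{type(exc).__name__}: {exc}"
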