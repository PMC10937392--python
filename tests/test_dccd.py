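import numpy as np
import pandas as pd
import pytest

from dccd import (
    ExpressionMatrix,
    dccd_score,
    dccd_score_cells,
    dccd_trajectory,
    pearson,
    simulate_dccd_cells,
)


def _expr(values, genes, samples):
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(values, float), index=genes, columns=samples),
        "tpm")


@pytest.fixture(scope="module")
def two_sample_case():
    genes = [f"g{i}" for i in range(8)]
    im2, im4 = ["g0", "g1"], ["g2", "g3"]
    vals = np.ones((8, 2))
    vals[0:2, 1] = 10  # sample B overexpresses IM2 set
    vals[2:4, 0] = 10  # sample A overexpresses IM4 set
    return _expr(vals, genes, ["A", "B"]), im2, im4


class TestDccdScore:
    def test_sign_symmetry_two_samples(self, two_sample_case):
        expr, im2, im4 = two_sample_case
        res = dccd_score(expr, im2, im4).set_index("entity_id")
        assert res.loc["A", "dccd_score"] > 0
        assert res.loc["A", "label"] == "IM4-like"
        assert res.loc["B", "dccd_score"] < 0
        assert res.loc["B", "label"] == "IM2-like"
        # z-scoring forces the two-entity scores to be exact negatives
        assert res.loc["A", "dccd_score"] == pytest.approx(
            -res.loc["B", "dccd_score"], abs=1e-12)

    def test_antisymmetry_under_set_swap(self, gradient_cohort, bulk_signatures):
        expr, _, _ = gradient_cohort
        fwd = dccd_score(expr, bulk_signatures["IM2"], bulk_signatures["IM4"])
        rev = dccd_score(expr, bulk_signatures["IM4"], bulk_signatures["IM2"])
        assert np.allclose(fwd.dccd_score.to_numpy(),
                           -rev.dccd_score.to_numpy(), atol=1e-12)

    def test_gradient_recovery(self, gradient_cohort, bulk_signatures):
        expr, _, truth = gradient_cohort
        res = dccd_score(expr, bulk_signatures["IM2"], bulk_signatures["IM4"])
        scores = res.set_index("entity_id")["dccd_score"]
        mix = truth.dccd_mixing_fraction
        r, _ = pearson(scores.loc[mix.index], mix)
        assert r >= 0.95

    def test_zscore_and_rank_invariants(self, gradient_cohort, bulk_signatures):
        expr, _, _ = gradient_cohort
        res = dccd_score(expr, bulk_signatures["IM2"], bulk_signatures["IM4"])
        assert abs(res.im2_score_z.mean()) < 1e-9
        assert abs(res.im4_score_z.mean()) < 1e-9
        assert res.im2_score_z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        assert abs(res.dccd_score.mean()) < 1e-9
        assert sorted(res["rank"]) == list(range(1, len(res) + 1))
        ordered = res.sort_values("rank")["dccd_score"].to_numpy()
        assert np.all(np.diff(ordered) >= -1e-12)

    def test_degenerate_cohort_rejected(self):
        genes = [f"g{i}" for i in range(6)]
        expr = _expr(np.tile(np.arange(6, dtype=float)[:, None] + 1, (1, 3)),
                     genes, ["a", "b", "c"])
        with pytest.raises(ValueError, match="degenerate"):
            dccd_score(expr, ["g0", "g1"], ["g2", "g3"])

    def test_monotone_transform_leaves_labels(self, two_sample_case):
        expr, im2, im4 = two_sample_case
        res_a = dccd_score(expr, im2, im4)
        cubed = ExpressionMatrix(expr.values ** 3, "tpm")
        res_b = dccd_score(cubed, im2, im4)
        assert res_a.label.tolist() == res_b.label.tolist()


class TestDccdScoreCells:
    def test_seventy_percent_sample_fraction(self):
        cells, truth = simulate_dccd_cells(
            n_samples=1, cells_per_sample=1000, im4_fractions=[0.7], seed=20)
        res, frac = dccd_score_cells(
            cells, list(truth.planted_markers["IM2-arch"]),
            list(truth.planted_markers["IM4-arch"]))
        assert 0.6 <= frac["P1"] <= 0.8

    def test_fraction_correlates_with_pseudobulk(self, cell_mixture):
        cells, truth = cell_mixture
        im2 = list(truth.planted_markers["IM2-arch"])
        im4 = list(truth.planted_markers["IM4-arch"])
        _, frac = dccd_score_cells(cells, im2, im4)
        pseudo = cells.counts.values.T.groupby(cells.sample_of_origin).mean().T
        pb = ExpressionMatrix(pseudo, "tpm")
        bulk = dccd_score(pb, im2, im4).set_index("entity_id")["dccd_score"]
        r, _ = pearson(frac.loc[bulk.index], bulk)
        assert r >= 0.9

    def test_identical_cells_rejected(self):
        from dccd import CellTable
        genes = [f"g{i}" for i in range(6)]
        cellids = [f"c{i}" for i in range(5)]
        counts = ExpressionMatrix(
            pd.DataFrame(3.0, index=genes, columns=cellids), "counts")
        table = CellTable(counts, pd.Series("M", index=cellids),
                          pd.Series("S1", index=cellids))
        with pytest.raises(ValueError, match="degenerate"):
            dccd_score_cells(table, ["g0", "g1"], ["g2", "g3"])


class TestDccdTrajectory:
    def test_window_one_is_reordering(self, gradient_cohort, bulk_signatures):
        expr, _, _ = gradient_cohort
        res = dccd_score(expr, bulk_signatures["IM2"], bulk_signatures["IM4"])
        genes = bulk_signatures["IM4"][:5]
        traj = dccd_trajectory(res, expr, genes, window=1)
        ordered = res.sort_values("rank")["entity_id"].tolist()
        assert np.allclose(traj.to_numpy(), expr.values.loc[genes, ordered])

    def test_monotone_gene_stays_monotone(self, gradient_cohort,
                                          bulk_signatures):
        expr, _, truth = gradient_cohort
        res = dccd_score(expr, bulk_signatures["IM2"], bulk_signatures["IM4"])
        # plant a synthetic perfectly-monotone gene: expression = mixing
        vals = expr.values.copy()
        vals.loc["planted_mix"] = truth.dccd_mixing_fraction[vals.columns] + 0.01
        expr2 = ExpressionMatrix(vals, "tpm")
        traj = dccd_trajectory(res, expr2, ["planted_mix"], window=11)
        row = traj.loc["planted_mix"].to_numpy()
        # a violation is a visible dip: a decrease > 1% of the row's range
        # (tiny fluctuations reflect local noise in the DCCD ordering, not
        # failure of the smoothing)
        span = row.max() - row.min()
        violations = (np.diff(row) < -0.01 * span).mean()
        assert violations <= 0.02
        assert row[-1] - row[0] > 0.9 * span  # overall monotone sweep

    def test_constant_gene_constant_row(self, gradient_cohort, bulk_signatures):
        expr, _, _ = gradient_cohort
        res = dccd_score(expr, bulk_signatures["IM2"], bulk_signatures["IM4"])
        vals = expr.values.copy()
        vals.loc["const_gene"] = 5.0
        traj = dccd_trajectory(res, ExpressionMatrix(vals, "tpm"),
                               ["const_gene"], window=11)
        assert np.allclose(traj.loc["const_gene"], 5.0)

    def test_even_window_rejected(self, gradient_cohort, bulk_signatures):
        expr, _, _ = gradient_cohort
        res = dccd_score(expr, bulk_signatures["IM2"], bulk_signatures["IM4"])
        with pytest.raises(ValueError, match="odd"):
            dccd_trajectory(res, expr, bulk_signatures["IM4"][:3], window=4)
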