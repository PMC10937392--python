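import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import bh_oracle, fisher_greater_oracle

from dccd import (
    CellTable,
    ExpressionMatrix,
    bh_adjust,
    da_scores,
    diff_abundance,
    fisher_one_sided,
    odds_ratio,
    or_grid,
    score_correlation,
    simulate_metabolome,
)


class TestFisherAndOddsRatio:
    def test_textbook_table(self):
        # (8,2,2,8): OR = (8*8)/(2*2) = 16, p from hypergeometric tail
        assert odds_ratio(8, 2, 2, 8) == pytest.approx(16.0)
        assert fisher_one_sided(8, 2, 2, 8) == pytest.approx(
            fisher_greater_oracle(8, 2, 2, 8), abs=1e-12)

    def test_haldane_only_with_zero_cell(self):
        assert odds_ratio(5, 0, 3, 7) == pytest.approx(
            (5.5 * 7.5) / (0.5 * 3.5))
        assert odds_ratio(5, 1, 3, 7) == pytest.approx((5 * 7) / (1 * 3))

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 11, size=4)
            if a + b == 0 or a + c == 0:
                continue
            assert fisher_one_sided(a, b, c, d) == pytest.approx(
                fisher_greater_oracle(int(a), int(b), int(c), int(d)),
                abs=1e-12)


class TestBhAdjust:
    def test_matches_literal_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_property_matches_oracle_and_is_monotone(self, p):
        p = np.array(p)
        q = bh_adjust(p)
        assert np.allclose(q, bh_oracle(p), atol=1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert ((q >= 0) & (q <= 1)).all()


def _mixture_cells(n_per=60):
    """Two clusters distributed unevenly over two subtypes' samples."""
    rng = np.random.default_rng(2)
    rows = []
    cells, clusters, samples = [], [], []
    i = 0
    for sample, subtype, p_c1 in (("s1", "IM2", 0.9), ("s2", "IM2", 0.9),
                                  ("s3", "IM4", 0.1), ("s4", "IM4", 0.1)):
        for _ in range(n_per):
            cells.append(f"c{i}"); i += 1
            clusters.append("C1" if rng.uniform() < p_c1 else "C2")
            samples.append(sample)
    counts = ExpressionMatrix(
        pd.DataFrame(rng.poisson(5, size=(10, len(cells))).astype(float),
                     index=[f"g{j}" for j in range(10)], columns=cells),
        "counts")
    table = CellTable(counts, pd.Series(clusters, index=cells),
                      pd.Series(samples, index=cells))
    return table, {"s1": "IM2", "s2": "IM2", "s3": "IM4", "s4": "IM4"}


class TestOrGrid:
    def test_preferential_cluster_called_enriched(self):
        table, subtype = _mixture_cells()
        grid = or_grid(table, subtype)
        row = grid[(grid.cluster == "C1") & (grid.subtype == "IM2")].iloc[0]
        assert row.call == "enriched" and row.odds_ratio > 1.5
        dep = grid[(grid.cluster == "C1") & (grid.subtype == "IM4")].iloc[0]
        assert dep.call == "depleted"

    def test_uniform_cluster_is_neutral(self):
        rng = np.random.default_rng(3)
        cells = [f"c{i}" for i in range(400)]
        clusters = ["C1" if i % 2 else "C2" for i in range(400)]
        samples = [f"s{i % 4}" for i in range(400)]
        counts = ExpressionMatrix(
            pd.DataFrame(rng.poisson(5, size=(5, 400)).astype(float),
                         index=[f"g{j}" for j in range(5)], columns=cells),
            "counts")
        table = CellTable(counts, pd.Series(clusters, index=cells),
                          pd.Series(samples, index=cells))
        grid = or_grid(table, {f"s{k}": ("IM2" if k < 2 else "IM4")
                               for k in range(4)})
        assert (grid.call == "neutral").all()
        assert np.allclose(grid.odds_ratio, 1.0, atol=0.05)

    def test_threshold_rule_is_conjunction(self):
        # OR above 1.5 with significant p -> enriched; OR 1.4 is neutral
        # regardless of p (the printed rule requires both conditions)
        table, subtype = _mixture_cells()
        grid = or_grid(table, subtype, or_hi=1e9)
        assert (grid.call != "enriched").all()

    def test_table_margins_sum_to_total(self):
        table, subtype = _mixture_cells()
        grid = or_grid(table, subtype)
        total = len(table.cell_ids)
        assert ((grid.a + grid.b + grid.c + grid.d) == total).all()


@pytest.fixture(scope="module")
def metabolome():
    pw = {"pwA": [f"a{i}" for i in range(10)],
          "pwB": [f"b{i}" for i in range(8)]}
    expr, truth = simulate_metabolome(
        pathways=pw, shifts={"pwA": (4, 1, 3.0)}, seed=4)
    return expr, truth, pw


class TestDiffAbundance:
    def test_planted_shift_called_up(self, metabolome):
        expr, truth, _ = metabolome
        diff = diff_abundance(expr, truth.group_labels)
        up = set(diff[diff.direction == "up"].feature)
        assert set(truth.metabolite_shifts["pwA"]["up"]) <= up

    def test_identical_groups_all_ns(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(size=(6, 6))
        expr = ExpressionMatrix(
            pd.DataFrame(np.column_stack([vals, vals]),
                         index=[f"m{i}" for i in range(6)],
                         columns=[f"t{i}" for i in range(6)]
                         + [f"n{i}" for i in range(6)]), "intensity")
        groups = pd.Series(["tumor"] * 6 + ["normal"] * 6,
                           index=expr.sample_ids)
        diff = diff_abundance(expr, groups)
        assert (diff.direction == "ns").all()

    def test_cutoff_conjunction(self, metabolome):
        """Effect passing log2fc but not p (or vice versa) stays ns."""
        expr, truth, _ = metabolome
        diff = diff_abundance(expr, truth.group_labels, log2fc_cutoff=1e9)
        assert (diff.direction == "ns").all()

    def test_type_i_error_calibration(self):
        rng = np.random.default_rng(6)
        vals = rng.lognormal(size=(2000, 40))
        expr = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"f{i}" for i in range(2000)],
                         columns=[f"s{i}" for i in range(40)]), "intensity")
        groups = pd.Series(["tumor"] * 20 + ["normal"] * 20,
                           index=expr.sample_ids)
        diff = diff_abundance(expr, groups)
        rate = (diff.p_value < 0.05).mean()
        assert 0.035 <= rate <= 0.065


class TestDaScores:
    def _diff(self, directions):
        return pd.DataFrame({
            "feature": [f"m{i}" for i in range(len(directions))],
            "log2fc": 0.0, "p_value": 1.0, "p_adj": 1.0,
            "direction": directions})

    def test_formula_four_up_one_down_of_ten(self):
        diff = self._diff(["up"] * 4 + ["down"] + ["ns"] * 5)
        da = da_scores(diff, {"p": [f"m{i}" for i in range(10)]})
        assert da.score.iloc[0] == pytest.approx(0.3)

    def test_all_up_is_one(self):
        diff = self._diff(["up"] * 6)
        da = da_scores(diff, {"p": [f"m{i}" for i in range(6)]})
        assert da.score.iloc[0] == 1.0

    def test_end_to_end_recovery(self):
        pw = {"pw": [f"m{i}" for i in range(10)]}
        expr, truth = simulate_metabolome(
            pathways=pw, shifts={"pw": (6, 2, 4.0)}, noise_sd=0.2, seed=7)
        diff = diff_abundance(expr, truth.group_labels)
        da = da_scores(diff, pw)
        assert da.score.iloc[0] == pytest.approx(0.4)

    def test_unmeasured_pathway_omitted(self):
        diff = self._diff(["up", "ns"])
        da = da_scores(diff, {"seen": ["m0"], "unseen": ["zz"]})
        assert da.pathway.tolist() == ["seen"]

    def test_antisymmetry_under_direction_swap(self):
        diff = self._diff(["up"] * 3 + ["down"] * 1 + ["ns"] * 2)
        swapped = diff.assign(direction=diff.direction.map(
            {"up": "down", "down": "up", "ns": "ns"}))
        pw = {"p": [f"m{i}" for i in range(6)]}
        assert da_scores(diff, pw).score.iloc[0] == pytest.approx(
            -da_scores(swapped, pw).score.iloc[0])


class TestScoreCorrelation:
    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        r, _ = score_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_collinear_three_points(self):
        r, p = score_correlation([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_independent_shuffle_near_zero(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=1000)
        y = rng.permutation(x)
        r, _ = score_correlation(x, y)
        assert abs(r) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            score_correlation([1, 1, 1], [1, 2, 3])
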