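import numpy as np
import pandas as pd
import pytest

from dccd import (
    simulate_bulk_cohort,
    simulate_dccd_cells,
    simulate_metabolome,
    simulate_sc_counts,
)


class TestSimulateScCounts:
    def test_same_seed_identical(self):
        a, _ = simulate_sc_counts(n_cells=200, n_genes=100,
                                  markers_per_cluster=10, seed=5)
        b, _ = simulate_sc_counts(n_cells=200, n_genes=100,
                                  markers_per_cluster=10, seed=5)
        assert a.counts.values.equals(b.counts.values)

    def test_different_seed_differs(self):
        a, _ = simulate_sc_counts(n_cells=200, n_genes=100,
                                  markers_per_cluster=10, seed=5)
        b, _ = simulate_sc_counts(n_cells=200, n_genes=100,
                                  markers_per_cluster=10, seed=6)
        assert not a.counts.values.equals(b.counts.values)

    def test_null_effect_gives_unit_mean_ratio(self):
        cells, truth = simulate_sc_counts(n_cells=2000, n_genes=200,
                                          markers_per_cluster=10,
                                          marker_log2fc=0.0, seed=1)
        counts = cells.counts.values
        lab = cells.cluster_label
        for cluster, markers in truth.planted_markers.items():
            for g in list(markers)[:3]:
                m_in = counts.loc[g, lab == cluster].mean()
                m_out = counts.loc[g, lab != cluster].mean()
                n_in = (lab == cluster).sum()
                se = counts.loc[g].std() / np.sqrt(n_in)
                assert abs(m_in - m_out) < 3 * se + 1e-9

    def test_nb_moments(self):
        """Sample mean/variance consistent with NB(m, phi): var ~ m + phi m^2."""
        phi = 0.4
        cells, _ = simulate_sc_counts(n_cells=5000, n_genes=300,
                                      markers_per_cluster=1,
                                      marker_log2fc=0.0,
                                      nb_dispersion=phi, seed=2)
        x = cells.counts.values.to_numpy()
        m = x.mean(axis=1)
        v = x.var(axis=1)
        expect = m + phi * m ** 2
        big = m > 2  # moment check is meaningful for non-sparse genes
        rel = np.abs(v[big] - expect[big]) / expect[big]
        assert np.median(rel) < 0.10

    def test_infeasible_marker_budget(self):
        with pytest.raises(ValueError, match="budget"):
            simulate_sc_counts(n_cells=10, n_genes=10, markers_per_cluster=5)

    def test_nonpositive_dispersion(self):
        with pytest.raises(ValueError, match="dispersion"):
            simulate_sc_counts(n_cells=10, n_genes=100,
                               markers_per_cluster=10, nb_dispersion=0.0)

    def test_bad_proportions(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_sc_counts(clusters=[("A", 0.5), ("B", 0.4)])


class TestSimulateBulkCohort:
    def test_noise_free_signature_is_exact_fourfold(self, bulk_signatures):
        expr, _, truth = simulate_bulk_cohort(
            n_samples=40, signatures=bulk_signatures, signature_log2fc=2.0,
            noise_sd=0.0, seed=3)
        labels = truth.bulk_subtype_labels
        im2 = labels.index[labels == "IM2"]
        other = labels.index[labels != "IM2"]
        sig = bulk_signatures["IM2"]
        ratio = expr.values.loc[sig, im2].mean(axis=1) \
            / expr.values.loc[sig, other].mean(axis=1)
        # IM2 genes are only boosted in IM2 samples, so the ratio is exactly 4
        assert np.allclose(ratio, 4.0)

    def test_gradient_blend_is_linear_in_mixing(self, bulk_signatures):
        expr, _, truth = simulate_bulk_cohort(
            n_samples=60, signatures=bulk_signatures, signature_log2fc=2.0,
            noise_sd=0.0, dccd_gradient=True, seed=4)
        labels = truth.bulk_subtype_labels
        mix = truth.dccd_mixing_fraction
        log2x = np.log2(expr.values)
        im4 = bulk_signatures["IM4"]
        baseline = log2x.loc[im4, labels == "IM2"].mean(axis=1)  # m=0 on IM4 genes
        for s in labels.index[labels.isin(["IM1", "IM3"])][:5]:
            boost = (log2x.loc[im4, s] - baseline).mean()
            assert boost == pytest.approx(2.0 * mix[s], abs=1e-9)

    def test_gradient_endpoints(self, gradient_cohort):
        _, _, truth = gradient_cohort
        mix = truth.dccd_mixing_fraction
        lab = truth.bulk_subtype_labels
        assert (mix[lab == "IM2"] == 0).all()
        assert (mix[lab == "IM4"] == 1).all()

    def test_median_survival_matches_exponential_closed_form(self):
        """KM median per subtype ~ ln(2)/hazard at n=500 (within 15%).

        The Kaplan-Meier median is used because the generator censors
        independently; the raw median of observed event times would be
        biased low.
        """
        from dccd import km_fit
        hz = {"IM1": 1 / 500.0, "IM2": 1 / 500.0,
              "IM3": 1 / 500.0, "IM4": 1 / 500.0}
        _, meta, _ = simulate_bulk_cohort(n_samples=500, seed=5,
                                          hazard_by_subtype=hz,
                                          noise_sd=0.5, n_genes=200)
        rec = pd.DataFrame({"sample_id": meta.index,
                            "time": meta["os_time"],
                            "event": meta["os_event"], "group": "all"})
        rec = rec[rec["time"] > 0]
        curve = km_fit(rec)["all"]
        km_median = curve.times[np.searchsorted(-curve.survival, -0.5)]
        expect = np.log(2) * 500
        assert abs(km_median - expect) / expect < 0.15

    def test_bad_proportions(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_bulk_cohort(subtype_proportions={"IM1": 0.5, "IM2": 0.4})


class TestSimulateMetabolome:
    def test_expected_da_score_recorded(self):
        pw = {"p": [f"m{i}" for i in range(10)]}
        _, truth = simulate_metabolome(pathways=pw, shifts={"p": (4, 1, 3.0)},
                                       seed=6)
        assert truth.expected_da_score["p"] == pytest.approx(0.3)

    def test_zero_effect_expects_zero_score(self):
        pw = {"p": [f"m{i}" for i in range(10)]}
        _, truth = simulate_metabolome(pathways=pw, shifts={"p": (4, 1, 0.0)},
                                       seed=6)
        assert truth.expected_da_score["p"] == 0.0

    def test_same_seed_identical(self):
        a, _ = simulate_metabolome(seed=9)
        b, _ = simulate_metabolome(seed=9)
        assert a.values.equals(b.values)

    def test_overfull_shift_rejected(self):
        pw = {"p": ["m1", "m2"]}
        with pytest.raises(ValueError, match="exceeds"):
            simulate_metabolome(pathways=pw, shifts={"p": (2, 1, 1.0)})


class TestSimulateDccdCells:
    def test_planted_fraction_matches_labels(self, cell_mixture):
        cells, truth = cell_mixture
        frac = (cells.cluster_label == "IM4-arch") \
            .groupby(cells.sample_of_origin).mean()
        planted = truth.dccd_mixing_fraction
        assert np.allclose(frac[planted.index], planted, atol=0.01)

    def test_determinism(self):
        a, _ = simulate_dccd_cells(n_samples=2, cells_per_sample=50,
                                   n_genes=100, seed=1)
        b, _ = simulate_dccd_cells(n_samples=2, cells_per_sample=50,
                                   n_genes=100, seed=1)
        assert a.counts.values.equals(b.counts.values)
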