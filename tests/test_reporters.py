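import numpy as np
import pytest
from scipy import stats as sps

from crestrack.geometry import HalfSpace, Sphere
from crestrack.reporters import (
    GroupSummary,
    background_subtract,
    classify_expression_state,
    classify_truth_expression,
    colocalize,
    count_cells_in_region,
    format_mean_sd,
    intensity_profile,
    mad_threshold,
    positive_fraction,
    welch_t_test,
)
from crestrack.simulate import apply_photoconversion


class TestWelch:
    def test_endothelial_count_worked_example(self):
        # control vs knockdown endothelial cell counts, from group summaries
        r = welch_t_test(GroupSummary(28.6, 3.6, 25), GroupSummary(12.8, 6.7, 28))
        assert abs(r.statistic - 10.7) / 10.7 < 0.025
        assert abs(r.df - 42.1) / 42.1 < 0.025
        assert r.p_value < 1e-12

    def test_guidance_knockdown_worked_example(self):
        r = welch_t_test(GroupSummary(25.3, 3.8, 22), GroupSummary(4.8, 2.7, 28))
        assert abs(r.df - 36.3) / 36.3 < 0.025
        assert abs(r.statistic - 20.9) / 20.9 < 0.025

    def test_hand_calculation(self):
        r = welch_t_test(GroupSummary(10, 1, 10), GroupSummary(8, 1, 10))
        assert np.isclose(r.statistic, 4.4721, atol=1e-4)
        assert np.isclose(r.df, 18.0)

    def test_identical_summaries(self):
        r = welch_t_test(GroupSummary(5, 2, 10), GroupSummary(5, 2, 10))
        assert r.statistic == 0.0 and np.isclose(r.p_value, 1.0)

    def test_antisymmetry(self):
        a, b = GroupSummary(12.0, 2.0, 14), GroupSummary(9.0, 4.0, 20)
        r1, r2 = welch_t_test(a, b), welch_t_test(b, a)
        assert np.isclose(r1.statistic, -r2.statistic)
        assert np.isclose(r1.df, r2.df) and np.isclose(r1.p_value, r2.p_value)

    def test_equal_variance_equal_n_df(self):
        r = welch_t_test(GroupSummary(3, 1.5, 12), GroupSummary(1, 1.5, 12))
        assert np.isclose(r.df, 2 * 12 - 2)

    def test_degenerate_zero_variance(self):
        r = welch_t_test(GroupSummary(3, 0, 5), GroupSummary(3, 0, 5))
        assert r.degenerate and r.p_value == 1.0

    def test_matches_scipy_from_samples(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(5, 2, 30), rng.normal(4, 3, 22)
        r = welch_t_test(GroupSummary.from_values(a), GroupSummary.from_values(b))
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert np.isclose(r.statistic, ref.statistic)
        assert np.isclose(r.p_value, ref.pvalue)

    def test_summary_validation_and_formatting(self):
        with pytest.raises(ValueError):
            GroupSummary(1.0, -0.1, 5)
        with pytest.raises(ValueError):
            GroupSummary(1.0, 0.1, 1)
        assert format_mean_sd(GroupSummary(28.6, 3.6, 25)) == "28.6 ± 3.6 (n = 25)"


class TestImageOps:
    def test_constant_image_subtracts_to_zero(self):
        img = np.full((4, 10, 10), 7.0)
        assert (background_subtract(img) == 0).all()

    def test_spike_survives_median_subtraction(self):
        img = np.full((1, 9, 9), 5.0)
        img[0, 4, 4] += 11.0
        out = background_subtract(img)
        assert np.isclose(out[0, 4, 4], 11.0)
        assert np.isclose(out.sum(), 11.0)

    def test_colocalize_zero_channel_gives_zero(self):
        a = np.zeros((2, 8, 8))
        b = np.random.default_rng(0).uniform(0, 10, (2, 8, 8))
        assert (colocalize(a, b) == 0).all()

    def test_colocalize_blob_product(self):
        b_level, c = 3.0, 10.0
        img = np.full((1, 20, 20), b_level)
        img[0, 8:12, 8:12] = c
        prod = colocalize(img, img)
        assert np.isclose(prod[0, 10, 10], (c - b_level) ** 2)
        assert prod[0, 0, 0] == 0.0

    def test_colocalize_commutative_and_shape_checked(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 5, (2, 6, 6))
        b = rng.uniform(0, 5, (2, 6, 6))
        assert np.allclose(colocalize(a, b), colocalize(b, a))
        with pytest.raises(ValueError):
            colocalize(a, b[:1])

    def test_disjoint_blobs_score_zero(self):
        a = np.zeros((1, 20, 20))
        b = np.zeros((1, 20, 20))
        a[0, 2:5, 2:5] = 9.0
        b[0, 14:17, 14:17] = 9.0
        _, scores = colocalize(a, b, detections=[(0, 3, 3), (0, 15, 15)])
        assert (scores == 0).all()


class TestExpressionClassification:
    def test_threshold_logic(self):
        assert classify_expression_state(0.0, 5.0) == "silenced"
        assert classify_expression_state(2.0, 5.0) == "active"
        assert classify_expression_state(0.0, 0.0) == "unclassifiable"
        assert classify_expression_state(1e-9, 0.0, ratio_threshold=0.0) == "active"

    def test_conversion_at_17_separates_the_waves_perfectly(self, default_truth):
        _, truth = default_truth
        conv = apply_photoconversion(truth, 17.0)
        states = classify_truth_expression(conv, 30.0)
        for c in conv.cells:
            if c.cell_id in states:
                want = "active" if c.population == "2NC" else "silenced"
                assert states[c.cell_id] == want


class TestFractionsAndCounts:
    def test_study_like_fraction(self):
        values = [1.0] * 23 + [0.0] * 24
        frac, a, n = positive_fraction(values, 0.5)
        assert (a, n) == (23, 47)
        assert np.isclose(frac, 23 / 47)

    def test_extremes(self):
        frac, a, n = positive_fraction([0.1, 0.2], 5.0)
        assert frac == 0.0
        frac, a, n = positive_fraction([0.1, 0.2], -np.inf)
        assert frac == 1.0

    def test_mad_threshold_scale(self):
        rng = np.random.default_rng(2)
        v = rng.normal(10, 2, 20000)
        thr = mad_threshold(v, k=3.0)
        assert abs(thr - 16.0) < 0.2

    def test_count_cells_in_region(self):
        pts = np.array([[0, 0, 0], [5, 0, 0], [0, 5, 0], [9, 9, 9.0]])
        assert count_cells_in_region(pts, Sphere((0, 0, 0), 6.0)) == 3
        assert count_cells_in_region(np.empty((0, 3)), Sphere((0, 0, 0), 6.0)) == 0
        half = HalfSpace((0, 0, 0), (1, 0, 0), 1.0)
        assert count_cells_in_region(pts, half) == 2


class TestIntensityProfile:
    def test_two_wave_profile_peaks_near_configured_times(self):
        # composition held fixed (no divisions) so the population mean
        # reflects the per-cell reporter dynamics
        from crestrack.simulate import build_embryo_model, simulate_populations
        from tests.conftest import coarse_config

        cfg = coarse_config(n_1nc=20, n_2nc=20, division_rate_per_h=0.0,
                            mixing_fraction=0.0, seed=1)
        truth = simulate_populations(build_embryo_model(cfg), cfg)
        prof = intensity_profile(truth, "wnt")
        cfg = truth.config
        t = prof.t_hpf
        # first wave: global argmax restricted to before 17 hpf
        early = (t < 17) & (prof.n_cells > 0)
        t1 = t[early][np.nanargmax(prof.mean_intensity[early])]
        assert abs(t1 - cfg.wnt_wave1_peak_hpf) <= 1.0
        late = (t > 18) & (prof.n_cells > 0)
        t2 = t[late][np.nanargmax(prof.mean_intensity[late])]
        assert abs(t2 - cfg.wnt_wave2_peak_hpf) <= 1.0

    def test_linearity_and_counts(self, default_truth):
        _, truth = default_truth
        prof = intensity_profile(truth, "wnt")
        assert (prof.n_cells >= 0).all()
        assert np.isnan(prof.mean_intensity[prof.n_cells == 0]).all()

    def test_wave2_positive_fraction_matches_config(self, default_truth):
        _, truth = default_truth
        frac = np.mean([c.wnt_positive for c in truth.founders()
                        if c.population == "2NC"])
        # Bernoulli(0.5) over 14 founders: generous band
        assert 0.2 <= frac <= 0.8
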