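import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from crestrack.circular import (
    AngleSample,
    angle_histogram,
    center_tracks,
    circular_distance_deg,
    circular_median,
    displacement_angles_deg,
    sample_displacement_angles,
    wallraff_test,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def grid_median_cost(angles):
    """Minimum summed circular distance over a 1-degree grid."""
    grid = np.arange(0.0, 360.0)
    costs = circular_distance_deg(grid[:, None], np.asarray(angles)[None, :]).sum(1)
    return costs.min()


def oracle_wallraff_p(a, b):
    """Exact two-sided Wallraff p by enumerating group assignments.

    Independent route: the U statistic is recomputed per split by direct
    pairwise comparison of the distance values (not via precomputed ranks).
    """
    da = circular_distance_deg(a, circular_median(a))
    db = circular_distance_deg(b, circular_median(b))
    pooled = np.concatenate([da, db])
    na, n = len(da), len(pooled)

    def u_of(idx_a):
        idx_a = set(idx_a)
        ua = 0.0
        for i in idx_a:
            for j in range(n):
                if j in idx_a:
                    continue
                if pooled[i] > pooled[j]:
                    ua += 1.0
                elif pooled[i] == pooled[j]:
                    ua += 0.5
        return ua

    mu = na * (n - na) / 2.0
    u_obs = u_of(range(na))
    dev = abs(u_obs - mu) - 1e-9
    count = sum(
        1 for idx in itertools.combinations(range(n), na) if abs(u_of(idx) - mu) >= dev
    )
    return count / comb(n, na)


# ---------------------------------------------------------------------------
# circular median
# ---------------------------------------------------------------------------


class TestCircularMedian:
    @pytest.mark.parametrize(
        "angles,expected",
        [([10, 20, 30], 20.0), ([350, 10, 30], 10.0), ([77], 77.0)],
    )
    def test_small_examples(self, angles, expected):
        assert circular_median(angles) == expected

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            circular_median([])

    @given(
        st.lists(st.integers(min_value=0, max_value=359), min_size=1, max_size=8)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_grid_minimization(self, angles):
        m = circular_median(angles)
        cost = circular_distance_deg(np.asarray(angles, float), m).sum()
        assert np.isclose(cost, grid_median_cost(angles))

    def test_tie_resolves_to_smallest_angle(self):
        # both 90 and 270 minimise for {0, 180} shifted samples
        assert circular_median([0.0, 180.0]) == 0.0


# ---------------------------------------------------------------------------
# displacement sampling and histogram
# ---------------------------------------------------------------------------


class TestDisplacementAngles:
    def test_pure_anterior_motion_is_zero_degrees(self):
        pos = np.zeros((21, 3))
        pos[:, 0] = np.arange(21.0)
        assert np.allclose(displacement_angles_deg(pos, 10), 0.0)

    def test_equal_anterior_and_distal_components_give_45(self):
        pos = np.zeros((21, 3))
        pos[:, 0] = np.arange(21.0)
        pos[:, 1] = np.arange(21.0)
        assert np.allclose(displacement_angles_deg(pos, 10), 45.0)

    def test_41_frames_stride_10_gives_4_vectors(self):
        pos = np.zeros((41, 3))
        pos[:, 0] = np.arange(41.0)
        assert len(displacement_angles_deg(pos, 10)) == 4

    def test_short_track_yields_empty_sample(self):
        assert len(displacement_angles_deg(np.zeros((5, 3)), 10)) == 0

    def test_small_steps_are_filtered(self):
        pos = np.zeros((21, 3))
        pos[:, 0] = np.arange(21.0) * 0.01
        assert len(displacement_angles_deg(pos, 10, min_step_um=0.5)) == 0

    def test_pooling_keeps_track_ids(self):
        pos = np.zeros((21, 3))
        pos[:, 0] = np.arange(21.0)
        sample = sample_displacement_angles({3: pos, 7: pos}, 10)
        assert sorted(set(sample.cell_ids)) == [3, 7]
        assert sample.n == 4


class TestHistogram:
    def test_half_open_binning(self):
        h = angle_histogram(AngleSample("x", [5.0, 15.0, 15.0]), 10.0)
        assert h.counts[0] == 1 and h.counts[1] == 2
        assert h.counts.sum() == 3

    def test_uniform_bin_centres(self):
        h = angle_histogram(AngleSample("x", np.arange(5.0, 360.0, 10.0)), 10.0)
        assert (h.counts == 1).all()

    def test_empty_sample_flags_median(self):
        h = angle_histogram(AngleSample("x", []), 10.0)
        assert h.counts.sum() == 0 and h.median_deg is None

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            angle_histogram(AngleSample("x", [1.0]), 7.0)


# ---------------------------------------------------------------------------
# Wallraff test
# ---------------------------------------------------------------------------


class TestWallraff:
    def test_identical_groups_give_p_one(self):
        a = AngleSample("a", [0.0, 5, 355, 10, 350])
        assert wallraff_test(a, AngleSample("b", a.angles_deg.copy())).p_value == 1.0

    def test_degenerate_distances_are_flagged(self):
        a = AngleSample("a", [10.0, 10.0, 10.0])
        b = AngleSample("b", [250.0, 250.0])
        r = wallraff_test(a, b)
        assert r.degenerate and r.p_value == 1.0

    def test_exact_p_matches_enumeration_oracle(self):
        a = AngleSample("a", [0.0, 5, 355, 10, 350])
        b = AngleSample("b", [0.0, 90, 270, 45, 315])
        r = wallraff_test(a, b)
        assert r.method == "wallraff-exact"
        assert np.isclose(r.p_value, oracle_wallraff_p(a.angles_deg, b.angles_deg))

    @pytest.mark.parametrize("trial", range(12))
    def test_random_small_samples_match_oracle(self, trial):
        rng = np.random.default_rng(trial)
        na = int(rng.integers(2, 7))
        nb = int(rng.integers(2, min(12 - na, 7) + 1))
        a = rng.integers(0, 360, na).astype(float)
        b = rng.integers(0, 360, nb).astype(float)
        r = wallraff_test(AngleSample("a", a), AngleSample("b", b))
        assert np.isclose(r.p_value, oracle_wallraff_p(a, b))

    def test_rotation_leaves_p_invariant_and_shifts_angles(self):
        rng = np.random.default_rng(5)
        a = rng.vonmises(0.5, 2.0, 30) * 180 / np.pi % 360
        b = rng.vonmises(1.5, 0.5, 25) * 180 / np.pi % 360
        r0 = wallraff_test(AngleSample("a", a), AngleSample("b", b))
        phi = 73.0
        r1 = wallraff_test(
            AngleSample("a", (a + phi) % 360), AngleSample("b", (b + phi) % 360)
        )
        assert np.isclose(r0.p_value, r1.p_value)
        assert np.isclose(
            (circular_median((a + phi) % 360) - circular_median(a)) % 360, phi
        )

    def test_large_sample_path_agrees_with_mannwhitney(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 360, 40)
        b = rng.uniform(0, 360, 35)
        r = wallraff_test(AngleSample("a", a), AngleSample("b", b))
        da = circular_distance_deg(a, circular_median(a))
        db = circular_distance_deg(b, circular_median(b))
        ref = sps.mannwhitneyu(da, db, alternative="two-sided", method="asymptotic")
        assert np.isclose(r.p_value, ref.pvalue)


class TestCenterTracks:
    def test_first_point_is_origin_and_translation_invariant(self):
        rng = np.random.default_rng(7)
        pos = rng.normal(0, 5, (20, 3))
        out, skipped = center_tracks({1: (0, pos)}, 5)
        assert skipped == 0
        assert np.allclose(out[1][0], 0.0)
        out2, _ = center_tracks({1: (0, pos + 123.4)}, 5)
        assert np.allclose(out[1], out2[1])

    def test_stationary_track_stays_at_origin(self):
        out, _ = center_tracks({1: (0, np.ones((10, 3)))}, 0)
        assert np.allclose(out[1], 0.0)

    def test_absent_tracks_are_skipped_and_counted(self):
        out, skipped = center_tracks({1: (10, np.zeros((5, 3)))}, 0)
        assert out == {} and skipped == 1
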