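"""Orientation/eye map computation, gradients, fractures, KL stability."""

import numpy as np
import pytest

from cortexmap.config import RcmParams
from cortexmap.map_analysis import (
    OrientationMap,
    compute_odm,
    compute_rcm,
    current_balance,
    dominance_fraction,
    find_fractures,
    find_pinwheel_like,
    gaussian_bar_template,
    kl_similarity,
    odm_separation_stats,
    orientation_gradient,
    osm_vector_sum,
)


class TestBarTemplate:
    @pytest.mark.parametrize("phi", [0.0, 45.0, 90.0, 135.0])
    @pytest.mark.parametrize("gamma", [-3.0, 0.0, 2.0])
    def test_zero_sum_for_every_phi_gamma(self, phi, gamma):
        t = gaussian_bar_template(phi, gamma, RcmParams(), window=19)
        assert t.sum() == pytest.approx(0.0, abs=1e-12)

    def test_horizontal_template_symmetric_under_y_flip(self):
        t = gaussian_bar_template(0.0, 0.0, RcmParams(), window=15)
        np.testing.assert_allclose(t, t[:, ::-1], atol=1e-12)

    def test_self_inner_product_exceeds_orthogonal(self):
        p = RcmParams()
        t0 = gaussian_bar_template(0.0, 0.0, p, window=15)
        t90 = gaussian_bar_template(90.0, 0.0, p, window=15)
        assert (t0 * t0).sum() > (t0 * t90).sum()


class TestRcm:
    def _plant(self, phi, gamma, window, noise=0.0, rng=None):
        p = RcmParams(gamma_range=(-4, 4))
        t = gaussian_bar_template(phi, gamma, p, window)
        w = np.clip(t - t.min(), 0, None)
        w = w / w.max()
        if noise and rng is not None:
            w = np.clip(w + noise * rng.random(w.shape), 0, 1)
        return w

    def test_planted_oblique_bar_is_recovered(self):
        w = self._plant(45.0, 0.0, 9)
        omap = compute_rcm(w[None], RcmParams(gamma_range=(-4, 4)), (1, 1))
        d = abs((omap.preference[0, 0] - 45.0 + 90.0) % 180.0 - 90.0)
        assert d <= 22.5

    def test_plant_and_recover_rate_at_least_95_percent(self):
        """Planted bars at all four orientations and random offsets are
        recovered by the template/vector-sum pipeline in >= 95% of cases."""
        rng = np.random.default_rng(17)
        params = RcmParams(gamma_range=(-4, 4))
        hits = total = 0
        for phi in (0.0, 45.0, 90.0, 135.0):
            for _ in range(50):
                gamma = float(rng.uniform(-2, 2))
                w = self._plant(phi, gamma, 9, noise=0.1, rng=rng)
                omap = compute_rcm(w[None], params, (1, 1))
                d = abs((omap.preference[0, 0] - phi + 90.0) % 180.0 - 90.0)
                hits += d <= 22.5
                total += 1
        assert hits / total >= 0.95

    def test_isotropic_neighborhood_is_flagged_undefined(self):
        w = np.full((1, 9, 9), 0.5)
        omap = compute_rcm(w, RcmParams(gamma_range=(-4, 4)), (1, 1))
        assert omap.undefined[0, 0]
        assert omap.selectivity[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_empty_neighborhood_is_flagged(self):
        w = np.zeros((1, 9, 9))
        omap = compute_rcm(w, RcmParams(gamma_range=(-4, 4)), (1, 1))
        assert omap.undefined[0, 0]

    def test_orthogonal_scores_cancel_in_vector_sum(self):
        # equal R at 0 and 90 only: doubled-angle vectors are antiparallel
        ang = np.deg2rad([0.0, 90.0, 180.0, 270.0])
        R = np.array([1.0, 0.0, 1.0, 0.0])
        assert np.hypot((R * np.cos(ang)).sum(), (R * np.sin(ang)).sum()) \
            == pytest.approx(0.0, abs=1e-12)


class TestOdm:
    def test_equal_weights_everywhere_is_all_binocular(self):
        s = np.full(16, 0.3)
        odm = compute_odm(s, s.copy(), (4, 4))
        assert (odm.label == 0).all()

    def test_argmax_labeling(self):
        odm = compute_odm(np.array([0.7]), np.array([0.3]), (1, 1), smoothing=0)
        assert odm.label[0, 0] == 1

    def test_median_filter_removes_speckle(self):
        sl = np.ones((5, 5))
        sr = np.zeros((5, 5))
        sr[2, 2] = 2.0  # single right-dominant speckle in a left patch
        from scipy import ndimage

        raw = np.sign(sl - sr).astype(int)
        oracle = ndimage.median_filter(raw, size=3, mode="wrap")
        odm = compute_odm(sl.ravel(), sr.ravel(), (5, 5))
        np.testing.assert_array_equal(odm.label, oracle)
        assert (odm.label == 1).all()

    def test_labels_invariant_to_common_rescaling(self, rng):
        sl = rng.random(64)
        sr = rng.random(64)
        a = compute_odm(sl, sr, (8, 8))
        b = compute_odm(3.7 * sl, 3.7 * sr, (8, 8))
        np.testing.assert_array_equal(a.label, b.label)

    def test_separation_stats_match_hand_computation(self):
        # two left-labeled neurons with diffs {0.1, 0.3}
        sl = np.array([0.6, 0.8])
        sr = np.array([0.5, 0.5])
        odm = compute_odm(sl, sr, (1, 2), smoothing=0)
        stats = odm_separation_stats(odm)
        assert stats["mean_left"] == pytest.approx(0.2)
        assert stats["std_left"] == pytest.approx(0.1)

    def test_identical_sums_give_zero_stats(self):
        s = np.full(9, 0.4)
        stats = odm_separation_stats(compute_odm(s, s.copy(), (3, 3)))
        assert stats["mean_left"] == 0.0 and stats["std_left"] == 0.0

    def test_dominance_fraction_formula(self):
        odm = compute_odm(np.array([0.855]), np.array([0.145]), (1, 1), smoothing=0)
        assert dominance_fraction(odm, "left") == pytest.approx(71.0)


class TestOsmVectorSum:
    def _quad(self, r0, r45, r90, r135):
        mk = lambda v: np.full((3, 3), float(v))
        return {0.0: mk(r0), 45.0: mk(r45), 90.0: mk(r90), 135.0: mk(r135)}

    def test_single_orientation_response(self):
        omap = osm_vector_sum(self._quad(1, 0, 0, 0), smoothing=0)
        assert omap.preference[0, 0] == pytest.approx(0.0)

    def test_equal_cardinal_and_oblique_mix(self):
        omap = osm_vector_sum(self._quad(1, 1, 0, 0), smoothing=0)
        assert omap.preference[0, 0] == pytest.approx(22.5)

    def test_isotropic_responses_cancel(self):
        omap = osm_vector_sum(self._quad(1, 1, 1, 1), smoothing=0)
        assert omap.selectivity[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_circular_mean_on_random_quadruples(self):
        """Angle-doubling algebra: the vector-sum preference equals the
        circular mean of the four orientations weighted by differential
        responses, for 1000 random rate quadruples."""
        rng = np.random.default_rng(4)
        quads = rng.random((1000, 4)) * 50
        for r0, r45, r90, r135 in quads:
            omap = osm_vector_sum(self._quad(r0, r45, r90, r135), smoothing=0)
            # brute-force oracle: sum unit vectors at doubled angles weighted
            # by the raw responses
            x = r0 * np.cos(0) + r45 * np.cos(np.pi / 2) \
                + r90 * np.cos(np.pi) + r135 * np.cos(3 * np.pi / 2)
            y = r0 * np.sin(0) + r45 * np.sin(np.pi / 2) \
                + r90 * np.sin(np.pi) + r135 * np.sin(3 * np.pi / 2)
            if np.hypot(x, y) < 1e-9:
                continue
            expected = (np.rad2deg(np.arctan2(y, x)) / 2.0) % 180.0
            d = abs((omap.preference[0, 0] - expected + 90.0) % 180.0 - 90.0)
            assert d < 1e-9


class TestGradients:
    def test_constant_map_has_zero_gradient(self):
        omap = OrientationMap(np.full((8, 8), 37.0), np.ones((8, 8)), "osm")
        assert orientation_gradient(omap).max() == pytest.approx(0.0, abs=1e-12)

    def test_two_half_planes_make_a_90_degree_fracture_line(self):
        pref = np.zeros((10, 10))
        pref[5:] = 90.0
        omap = OrientationMap(pref, np.ones_like(pref), "osm")
        grad = orientation_gradient(omap)
        report = find_fractures(grad)
        assert grad[4].max() == pytest.approx(90.0)
        assert len(report["lines"]) >= 1
        # boundary rows are detected, interior is quiet
        assert grad[1:4].max() == 0.0

    def test_wraparound_angles_use_circular_metric(self):
        pref = np.zeros((4, 4))
        pref[:, 1] = 178.0
        pref[:, 2] = 2.0
        omap = OrientationMap(pref, np.ones_like(pref), "osm")
        grad = orientation_gradient(omap)
        # neighbor pair 178 vs 2 differs by 4 degrees, not 176
        assert grad[0, 1] == pytest.approx(4.0, abs=1e-9)

    def test_gradient_invariant_to_global_rotation(self, rng):
        pref = rng.random((12, 12)) * 180.0
        g1 = orientation_gradient(OrientationMap(pref, np.ones_like(pref), "osm"))
        g2 = orientation_gradient(
            OrientationMap((pref + 57.0) % 180.0, np.ones_like(pref), "osm"))
        np.testing.assert_allclose(g1, g2, atol=1e-9)

    def test_synthetic_pinwheel_detected_by_winding(self):
        yy, xx = np.mgrid[0:21, 0:21].astype(float) - 10.0
        pref = (np.rad2deg(np.arctan2(yy, xx)) / 2.0) % 180.0
        omap = OrientationMap(pref, np.ones_like(pref), "osm")
        mask = find_pinwheel_like(omap)
        ys, xs = np.nonzero(mask[2:-2, 2:-2])
        assert len(ys) >= 1
        assert np.all(np.abs(ys + 2 - 10) <= 2) and np.all(np.abs(xs + 2 - 10) <= 2)


class TestKlSimilarity:
    def test_identical_sets_give_zero(self, rng):
        w = rng.random(500)
        assert kl_similarity(w, w.copy()) == 0.0

    def test_symmetry(self, rng):
        a, b = rng.random(400), rng.random(400) ** 2
        assert kl_similarity(a, b) == pytest.approx(kl_similarity(b, a), rel=1e-12)

    def test_three_bin_toy_value_matches_hand_evaluation(self):
        # construct weight sets whose 3-bin histograms are h1=(2,1,1), h2=(1,2,1)
        w1 = [0.1, 0.2, 0.5, 0.9]
        w2 = [0.1, 0.4, 0.5, 0.9]
        p1 = np.array([2, 1, 1]) / 2.0  # max-normalized
        p2 = np.array([1, 2, 1]) / 2.0
        expected = 0.5 * ((p1 - p2) * np.log(p1 / p2)).sum()
        assert kl_similarity(w1, w2, n_bins=3) == pytest.approx(expected, rel=1e-9)

    def test_nonnegative_on_random_pairs(self, rng):
        for _ in range(20):
            a = rng.random(rng.integers(10, 200))
            b = rng.random(rng.integers(10, 200))
            assert kl_similarity(a, b) >= 0.0

    def test_proper_normalization_variant(self, rng):
        a, b = rng.random(300), rng.random(300)
        s = kl_similarity(a, b, proper_normalization=True)
        assert s >= 0.0
        assert kl_similarity(a, a, proper_normalization=True) == 0.0


class TestCurrentBalance:
    def test_no_inhibition_trace_equals_excitatory_mean(self):
        exc = np.full(600, 2.5)
        trace = current_balance(exc, np.zeros(600), window=200)
        np.testing.assert_allclose(trace.balance_instant, 2.5)
        assert (trace.balance_instant > 0).all()

    def test_balanced_currents_trace_near_zero(self, rng):
        exc = 1.0 + 0.01 * rng.standard_normal(1000)
        trace = current_balance(exc, np.ones(1000), window=200)
        np.testing.assert_allclose(trace.balance_instant, 0.0, atol=0.01)

    def test_window_blocking_and_running_mean(self):
        vals = np.concatenate([np.full(200, 4.0), np.full(200, 2.0)])
        trace = current_balance(vals, np.zeros(400), window=200)
        np.testing.assert_allclose(trace.balance_instant, [4.0, 2.0])
        np.testing.assert_allclose(trace.balance_running, [4.0, 3.0])
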