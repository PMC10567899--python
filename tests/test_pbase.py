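import numpy as np
import pytest

from fluoroi.pbase import (PbaseConfig, estimate_baseline,
                           estimate_mask_threshold, fit_polynomial_baseline,
                           guidance_scale_space, guidance_signal,
                           hampel_cleanup, range_projection, section_edges,
                           temporal_mean_cleanup)
from fluoroi.stack_io import FluorescenceStack
from fluoroi.synthetic import (SyntheticRoi, SyntheticSpec, TransientSpec,
                               dichotomy_configs, disk_footprint,
                               generate_fig_dichotomy_fixture, generate_movie)


class TestTemporalMeanCleanup:
    def test_printed_arithmetic_example(self):
        # mean of [1,1,1,1,100] is 20.8; population sigma ~39.6; with n=1
        # the threshold ~60.4 excludes only the 100
        trace = [1, 1, 1, 1, 100]
        mu = 20.8
        sigma = np.sqrt(((np.array(trace) - mu) ** 2).mean())
        assert sigma == pytest.approx(39.6, abs=0.01)
        vals, excl = temporal_mean_cleanup(trace, 1.0)
        assert list(excl) == [False, False, False, False, True]
        np.testing.assert_array_equal(vals, trace)

    def test_constant_trace_excludes_nothing(self):
        _, excl = temporal_mean_cleanup([5.0] * 10, 1.0)
        assert not excl.any()

    def test_huge_n_excludes_nothing(self, rng):
        trace = rng.normal(size=50)
        vals, excl = temporal_mean_cleanup(trace, 1e6)
        assert not excl.any()
        np.testing.assert_array_equal(vals, trace)

    def test_retained_values_unaltered(self, rng):
        trace = rng.normal(size=30)
        vals, excl = temporal_mean_cleanup(trace, 1.5)
        np.testing.assert_array_equal(vals[~excl], np.asarray(trace)[~excl])


class TestHampelCleanup:
    def test_isolated_spike(self):
        _, excl = hampel_cleanup([0, 0, 0, 10, 0, 0, 0], window=5, n_sigma=3)
        assert list(excl) == [False, False, False, True, False, False, False]

    def test_monotone_ramp_clean(self):
        _, excl = hampel_cleanup(np.arange(10.0), window=3, n_sigma=3)
        assert not excl.any()

    def test_matches_bruteforce_oracle_with_planted_spikes(self, rng):
        trace = rng.normal(0, 1, size=60)
        spikes = [10, 30, 50]
        trace[spikes] += 20.0
        window, n_sigma = 7, 3.0
        _, excl = hampel_cleanup(trace, window, n_sigma)

        half = window // 2
        oracle = np.zeros(60, dtype=bool)
        for t in range(60):
            win = trace[max(0, t - half):t + half + 1]
            med = np.median(win)
            mad = np.median(np.abs(win - med))
            oracle[t] = abs(trace[t] - med) > n_sigma * 1.4826 * mad
        np.testing.assert_array_equal(excl, oracle)
        assert all(excl[s] for s in spikes)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            hampel_cleanup(np.arange(10.0), window=4, n_sigma=3)


class TestGuidanceSignal:
    def test_two_exact_halves_min_error(self):
        trace = [1, 1, 1, 1, 3, 3, 3, 3]
        np.testing.assert_array_equal(guidance_signal(trace, max_scale=1,
                                                      mode="min_error"), trace)

    def test_four_sections_minima(self):
        trace = [2, 1, 2, 2, 5, 5, 4, 5]
        g = guidance_signal(trace, max_scale=2, mode="minima")
        np.testing.assert_array_equal(g, [1, 1, 2, 2, 5, 5, 4, 4])

    def test_maxima_on_constant(self):
        g = guidance_signal([7.0] * 16, max_scale=3, mode="maxima")
        np.testing.assert_array_equal(g, [7.0] * 16)

    def test_sections_cover_time_axis_disjointly(self):
        for T in (8, 13, 100, 37):
            for k in (1, 2, 3):
                edges = section_edges(T, k)
                assert edges[0] == 0 and edges[-1] == T
                assert np.all(np.diff(edges) >= 1)
                assert len(edges) == 2 ** k + 1

    def test_section_constants_match_bruteforce(self, rng):
        trace = rng.normal(size=32)
        excl = rng.random(32) < 0.2
        if excl.all():
            excl[0] = False
        for mode, fn in (("minima", np.min), ("maxima", np.max),
                         ("min_error", np.mean)):
            g = guidance_signal(trace, excl, max_scale=3, mode=mode)
            edges = section_edges(32, 3)
            for i in range(len(edges) - 1):
                seg = trace[edges[i]:edges[i + 1]]
                keep = ~excl[edges[i]:edges[i + 1]]
                if keep.any():
                    expected = fn(seg[keep])
                    np.testing.assert_allclose(g[edges[i]:edges[i + 1]], expected)

    def test_empty_section_inherits_neighbor(self):
        trace = np.arange(8.0)
        excl = np.zeros(8, dtype=bool)
        excl[6:] = True  # last quarter fully excluded at scale 2
        g = guidance_signal(trace, excl, max_scale=2, mode="min_error")
        np.testing.assert_allclose(g[6:], g[4:6])  # inherited from section 3

    def test_all_excluded_is_error(self):
        with pytest.raises(ValueError, match="empty guidance section"):
            guidance_signal(np.arange(8.0), np.ones(8, dtype=bool), max_scale=2)

    def test_scale_space_has_m_levels(self):
        scales = guidance_scale_space(np.arange(16.0), max_scale=3)
        assert len(scales) == 3
        assert all(len(s) == 16 for s in scales)


class TestPolynomialFit:
    def test_exact_degree2_representation(self):
        x = np.linspace(-1, 1, 50)
        guidance = 3.0 + 2.0 * x - 1.5 * x ** 2
        f0 = fit_polynomial_baseline(guidance, 2)
        np.testing.assert_allclose(f0, guidance, rtol=1e-8)

    def test_degree0_is_mean(self, rng):
        guidance = rng.normal(size=20)
        f0 = fit_polynomial_baseline(guidance, 0)
        np.testing.assert_allclose(f0, np.full(20, guidance.mean()), atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            T = int(rng.integers(8, 40))
            deg = int(rng.integers(0, 5))
            guidance = rng.normal(size=T)
            f0 = fit_polynomial_baseline(guidance, deg)
            x = np.linspace(-1, 1, T)
            V = np.vander(x, deg + 1, increasing=True)
            coef = np.linalg.solve(V.T @ V, V.T @ guidance)
            np.testing.assert_allclose(f0, V @ coef, atol=1e-6)

    def test_degree_too_high(self):
        with pytest.raises(ValueError):
            fit_polynomial_baseline(np.ones(3), 3)


class TestRangeProjection:
    def test_constant_pixel_zero(self):
        dff = np.zeros((5, 2, 2))
        np.testing.assert_array_equal(range_projection(dff), np.zeros((2, 2)))

    def test_arithmetic(self):
        dff = np.array([-0.1, 0.4, 0.2])[:, None, None]
        assert range_projection(dff)[0, 0] == pytest.approx(0.5)

    def test_matches_scan_oracle(self, rng):
        dff = rng.normal(size=(20, 6, 6))
        R = range_projection(dff)
        for y in range(6):
            for x in range(6):
                assert R[y, x] == dff[:, y, x].max() - dff[:, y, x].min()


class TestOtsuThreshold:
    def test_bimodal_separates(self):
        R = np.concatenate([np.zeros(50), np.ones(50)]).reshape(10, 10)
        thr = estimate_mask_threshold(R)
        assert 0.0 < thr < 1.0

    def test_matches_exhaustive_scan(self, rng):
        R = np.concatenate([rng.normal(0.1, 0.03, 300),
                            rng.normal(0.9, 0.1, 150)]).reshape(18, 25)
        thr = estimate_mask_threshold(R)
        hist, edges = np.histogram(R.ravel(), bins=256)
        centers = (edges[:-1] + edges[1:]) / 2

        def between_class_var(k):
            w0, w1 = hist[:k].sum(), hist[k:].sum()
            if w0 == 0 or w1 == 0:
                return -1.0
            mu0 = (hist[:k] * centers[:k]).sum() / w0
            mu1 = (hist[k:] * centers[k:]).sum() / w1
            return w0 * w1 * (mu0 - mu1) ** 2

        best_var = max(between_class_var(k) for k in range(1, 256))
        # the returned threshold must attain the maximal between-class
        # variance (near-empty bins create tie plateaus, so compare the
        # attained variance, not the raw threshold value)
        k_thr = int(np.searchsorted(centers, thr, side="right"))
        assert between_class_var(k_thr) == pytest.approx(best_var, rel=1e-9)

    def test_shift_equivariance(self, rng):
        R = rng.random((12, 12))
        thr = estimate_mask_threshold(R)
        thr_shifted = estimate_mask_threshold(R + 2.5)
        bin_width = np.ptp(R) / 256
        assert thr_shifted - thr == pytest.approx(2.5, abs=bin_width + 1e-12)

    def test_constant_range_image_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_mask_threshold(np.full((4, 4), 0.3))


def _poly_stack(rng, T=64, H=6, W=6):
    """Noiseless stack whose pixels are gentle degree-<=4 polynomials."""
    x = np.linspace(-1, 1, T)
    coeffs = np.zeros((5, H, W))
    coeffs[0] = rng.uniform(80, 120, (H, W))
    for d in range(1, 5):
        coeffs[d] = rng.uniform(-4, 4, (H, W))
    powers = x[:, None] ** np.arange(5)[None, :]
    data = np.tensordot(powers, coeffs, axes=(1, 0))
    return FluorescenceStack(data=data)


class TestEstimateBaseline:
    def test_pure_polynomial_recovery_both_cleanups(self, rng):
        """Transient-free polynomial input of degree <= fit degree is
        recovered essentially exactly with full-resolution guidance."""
        stack = _poly_stack(rng)
        for cleanup in ("temporal_mean", "hampel"):
            cfg = PbaseConfig(cleanup=cleanup, n_sigma=4.0, hampel_window=5,
                              max_scale=6, poly_degree=4, mask_threshold=0.0)
            res = estimate_baseline(stack, cfg)
            rel = np.max(np.abs(res.f0 - stack.data) / stack.data)
            assert rel < 1e-6
            assert np.max(np.abs(res.dff)) < 1e-6

    def test_transient_amplitude_recovered(self):
        """Planted 1.0-dff events on a quadratic drift come back within 10%
        on event pixels while drift-only pixels stay quiet."""
        fp = disk_footprint(4, 4, 2.0)
        spec = SyntheticSpec(
            shape=(200, 10, 10),
            baseline_coeffs=np.array([100.0, 8.0, -6.0]),
            rois=[SyntheticRoi(fp, [TransientSpec(46.0, 1.0, 6.0),
                                    TransientSpec(110.0, 1.0, 6.0),
                                    TransientSpec(164.0, 1.0, 6.0)])],
            frame_interval=1.0)
        stack, truth = generate_movie(spec)
        cfg = PbaseConfig(cleanup="temporal_mean", n_sigma=2.0, max_scale=3,
                          guidance_mode="min_error", poly_degree=2,
                          mask_threshold=0.0)
        res = estimate_baseline(stack, cfg)
        for (y, x) in fp:
            peak = res.dff[:, y, x].max()
            assert abs(peak - 1.0) <= 0.1
        quiet = ~truth.footprints[0]
        assert np.max(np.abs(res.dff[:, quiet])) < 0.1

    def test_mask_semantics_and_fit_count(self):
        fp = disk_footprint(4, 4, 2.0)
        spec = SyntheticSpec(
            shape=(64, 12, 12), baseline_coeffs=np.array([100.0]),
            rois=[SyntheticRoi(fp, [TransientSpec(30.0, 1.5, 6.0)])],
            noise_sigma=1.0, frame_interval=1.0, seed=7)
        stack, truth = generate_movie(spec)
        res = estimate_baseline(stack, PbaseConfig(mask_threshold="otsu"))
        assert res.mask.any() and not res.mask.all()
        assert np.all(res.dff[:, res.mask] == 0.0)
        assert np.all(res.range_projection[res.mask] == 0.0)
        assert res.n_fitted == int((~res.mask).sum())
        # masked pixels keep their recorded time course as F0
        np.testing.assert_array_equal(res.f0[:, res.mask], stack.data[:, res.mask])

    def test_cleanup_dichotomy_on_slow_ramp(self):
        """Whole-trace mean/sigma clean-up keeps a slow late rise out of F0
        (it survives in dff) while the sliding Hampel clean-up follows and
        absorbs it."""
        stack, truth = generate_fig_dichotomy_fixture(ramp_height=0.5)
        mean_cfg, hampel_cfg = dichotomy_configs()
        tail = slice(-15, None)
        dff_mean = estimate_baseline(stack, mean_cfg).dff[tail, 0, 0].max()
        dff_hampel = estimate_baseline(stack, hampel_cfg).dff[tail, 0, 0].max()
        assert dff_mean >= 0.4       # >= 80% of the 0.5 ramp preserved
        assert dff_hampel <= 0.1     # >= 80% absorbed into F0

    def test_no_ramp_regime_modes_agree(self):
        stack, _ = generate_fig_dichotomy_fixture(with_ramp=False)
        mean_cfg, hampel_cfg = dichotomy_configs()
        pk_mean = estimate_baseline(stack, mean_cfg).dff[:, 0, 0].max()
        pk_hampel = estimate_baseline(stack, hampel_cfg).dff[:, 0, 0].max()
        assert abs(pk_mean - pk_hampel) < 0.05

    def test_nonpositive_baseline_reported_with_pixel(self):
        data = np.ones((8, 3, 3)) * 50
        data[:, 1, 2] = np.linspace(-5, 5, 8)  # mean < 0 at (1, 2)
        with pytest.raises(ValueError, match=r"y=1, x=2"):
            estimate_baseline(FluorescenceStack(data=data),
                              PbaseConfig(mask_threshold=0.0, max_scale=1,
                                          poly_degree=1))
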