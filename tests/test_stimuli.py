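"""Background injection, retinal waves, spike encoding and image pipeline."""

import numpy as np
import pytest
from scipy import stats

from cortexmap.config import NoiseParams, RcmParams, RetinalWaveParams, StereoParams
from cortexmap.map_analysis import gaussian_bar_template
from cortexmap.stimuli import (
    StimulusFrame,
    background_injection,
    downsample,
    encode_poisson,
    generate_flag_pattern,
    generate_retinal_wave,
    make_on_off,
    make_stereo_pair,
    route_on_off,
    synthetic_natural_surrogate,
)


class TestBackgroundInjection:
    def test_mu_one_injects_nobody(self, rng):
        inj = background_injection(10_000, NoiseParams(mu=1.0), rng)
        assert np.count_nonzero(inj) == 0

    def test_injected_fraction_matches_printed_formula(self, rng):
        # u(r) = 1 iff r >= mu, so mu = 0.65 injects 35% of neurons
        params = NoiseParams(mu=0.65)
        inj = background_injection(200_000, params, rng)
        assert np.count_nonzero(inj) / inj.size == pytest.approx(0.35, abs=0.01)

    def test_injected_magnitude_is_printed_product(self, rng):
        params = NoiseParams(A=1.07, mu=0.0)  # everyone injected
        inj = background_injection(100, params, rng)
        np.testing.assert_allclose(inj, 1.07 * 0.00125)

    def test_fraction_override(self, rng):
        params = NoiseParams(mu=0.65, inject_fraction=0.6)
        inj = background_injection(200_000, params, rng)
        assert np.count_nonzero(inj) / inj.size == pytest.approx(0.6, abs=0.01)


class TestRetinalWaves:
    def test_no_sites_means_blank_frames(self, rng):
        frames = generate_retinal_wave(RetinalWaveParams(grid=32, n_sites=0), rng)
        assert all(not f.any() for f in frames)

    def test_one_wave_has_duration_frames_and_contiguous_swath(self, rng):
        params = RetinalWaveParams(grid=64, n_sites=1, duration=10, velocity=2)
        frames = generate_retinal_wave(params, rng)
        assert len(frames) == 10
        union = np.maximum.reduce([f > 0 for f in frames]).astype(int)
        # support spans roughly velocity*duration plus the burst window
        ys, xs = np.nonzero(union)
        extent = max(ys.max() - ys.min(), xs.max() - xs.min())
        assert extent >= params.velocity * (params.duration - 1) - 1

    def test_cumulative_coverage_over_many_waves(self):
        rng = np.random.default_rng(0)
        params = RetinalWaveParams(grid=24, n_sites=2, burst_size=6)
        covered = np.zeros((24, 24), dtype=bool)
        for _ in range(120):
            for f in generate_retinal_wave(params, rng):
                covered |= f > 0
        assert covered.all()

    def test_directions_drawn_uniformly(self):
        rng = np.random.default_rng(1)
        params = RetinalWaveParams(grid=48, n_sites=1, duration=4)
        # recover the direction from the displacement of the brightest pixel
        dirs = []
        for _ in range(400):
            frames = generate_retinal_wave(params, rng)
            c0 = np.unravel_index(np.argmax(frames[0]), frames[0].shape)
            c1 = np.unravel_index(np.argmax(frames[3]), frames[3].shape)
            dy = (c1[0] - c0[0] + 24) % 48 - 24
            dx = (c1[1] - c0[1] + 24) % 48 - 24
            dirs.append((np.sign(dy), np.sign(dx)))
        counts = {d: dirs.count(d) for d in set(dirs)}
        assert len(counts) == 8
        freqs = np.array(list(counts.values())) / len(dirs)
        assert np.all(np.abs(freqs - 1 / 8) < 0.07)

    def test_downsampling_preserves_mean_intensity(self, rng):
        frame = rng.random((48, 48))
        small = downsample(frame, (24, 24))
        assert small.mean() == pytest.approx(frame.mean(), rel=1e-9)
        odd = downsample(frame, (18, 18))  # non-divisible path
        assert odd.mean() == pytest.approx(frame.mean(), abs=0.02)


class TestPoissonEncoding:
    def test_blank_frame_emits_no_spikes(self, rng):
        spikes = encode_poisson(np.zeros((8, 8)), 100, rng)
        assert spikes.sum() == 0

    def test_nonpositive_duration_rejected(self, rng):
        with pytest.raises(ValueError):
            encode_poisson(np.ones((4, 4)), 0, rng)

    def test_isi_distribution_matches_poisson_pmf(self):
        # constant frame: ISIs are Poisson(isi_base); chi-square against the
        # closed form lambda^x e^-lambda / x!
        rng = np.random.default_rng(3)
        lam = 5.0
        spikes = encode_poisson(np.full((40, 40), 0.7), 2000, rng, isi_base_ms=lam)
        isis = []
        for row in spikes:
            t = np.flatnonzero(row)
            isis.extend(np.diff(t))
        isis = np.asarray(isis)
        assert isis.size > 10_000
        kmax = 14
        observed = np.bincount(isis, minlength=kmax + 1)[1:kmax + 1].astype(float)
        pmf = stats.poisson.pmf(np.arange(1, kmax + 1), lam)
        pmf = np.maximum(pmf, 1e-12)
        # the 1 ms floor folds P(0) into the first bin
        pmf[0] += stats.poisson.pmf(0, lam)
        expected = pmf / pmf.sum() * observed.sum()
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=kmax - 1)

    def test_zero_isi_probability_closed_form(self):
        assert stats.poisson.pmf(0, 5.0) == pytest.approx(np.exp(-5.0), rel=1e-12)
        assert np.exp(-5.0) == pytest.approx(6.74e-3, abs=5e-5)

    def test_brighter_frames_spike_at_least_as_much(self):
        means = []
        for level in (0.2, 0.5, 0.9):
            rng = np.random.default_rng(42)  # matched seeds
            spikes = encode_poisson(np.full((16, 16), level), 400, rng)
            means.append(spikes.sum())
        assert means[0] <= means[1] <= means[2]


class TestStereoPair:
    def test_identity_transform_copies_frame(self, rng):
        frame = StimulusFrame(rng.random((32, 32)))
        params = StereoParams(max_shift=0, scale_range=(1.0, 1.0))
        left, right = make_stereo_pair(frame, params, rng)
        np.testing.assert_allclose(left.pixels, right.pixels, atol=1e-12)
        assert left.eye == "left" and right.eye == "right"

    def test_pure_shift_displaces_columns(self, rng):
        frame = np.zeros((24, 24))
        frame[:, 5] = 1.0
        from cortexmap.stimuli import affine_resample

        shifted = affine_resample(frame, shift=(0, 10), scale=1.0)
        assert shifted[:, 15].mean() == pytest.approx(1.0)
        assert shifted[:, 5].mean() == pytest.approx(0.0, abs=1e-9)

    def test_scaling_matches_independent_affine_oracle(self):
        # a horizontal ramp scaled about the center: oracle via map_coordinates
        from scipy import ndimage

        from cortexmap.stimuli import affine_resample

        ramp = np.tile(np.linspace(0, 1, 33), (33, 1))
        s = 1.025
        ours = affine_resample(ramp, shift=(0, 0), scale=s)
        center = (33 - 1) / 2.0
        yy, xx = np.mgrid[0:33, 0:33].astype(float)
        coords = np.array([(yy - center) / s + center, (xx - center) / s + center])
        oracle = ndimage.map_coordinates(ramp, coords, order=1, mode="nearest")
        np.testing.assert_allclose(ours, oracle, atol=1e-9)


class TestOnOff:
    def test_uniform_midgray_gives_equal_channels(self):
        frame = StimulusFrame(np.full((16, 16), 0.5))
        on, off = make_on_off(frame, "one_minus")
        np.testing.assert_allclose(on.pixels, off.pixels)

    def test_white_pixel_is_dark_in_off_channel(self):
        px = np.zeros((8, 8))
        px[4, 4] = 1.0
        on, off = make_on_off(StimulusFrame(px), "one_minus")
        assert off.pixels[4, 4] == 0.0
        on, off = make_on_off(StimulusFrame(px), "mean_centered")
        assert off.pixels[4, 4] == 0.0

    def test_checkerboard_off_is_complement(self):
        board = np.indices((8, 8)).sum(axis=0) % 2
        on, off = make_on_off(StimulusFrame(board.astype(float)), "one_minus")
        np.testing.assert_allclose(off.pixels, 1.0 - board)

    def test_routing_packs_halves(self):
        px = np.full((48, 48), 0.5)
        on, off = make_on_off(StimulusFrame(px), "one_minus")
        rgc = route_on_off(on, off, (48, 48))
        assert rgc.shape == (48, 48)
        np.testing.assert_allclose(rgc[:24], 0.5)
        np.testing.assert_allclose(rgc[24:], 0.5)


def _orientation_energy(pixels, window=17):
    """Template-matched oriented energy at the four canonical orientations."""
    params = RcmParams(sigma_a=1.5, sigma_b=4.0)
    img = pixels - pixels.mean()
    energies = {}
    for phi in (0.0, 45.0, 90.0, 135.0):
        best = 0.0
        for gamma in range(-4, 5):
            t = gaussian_bar_template(phi, gamma, params, window)
            from scipy import signal

            resp = signal.fftconvolve(img, t, mode="valid")
            best = max(best, float(np.abs(resp).mean()))
        energies[phi] = best
    return energies


class TestPatternGenerators:
    def test_flag_energy_concentrates_on_cardinal_orientations(self):
        rng = np.random.default_rng(8)
        ratios = []
        for _ in range(12):
            flag = generate_flag_pattern(rng)
            e = _orientation_energy(flag.pixels)
            cardinal = e[0.0] + e[90.0]
            oblique = e[45.0] + e[135.0]
            ratios.append(cardinal / max(oblique, 1e-12))
        assert np.mean(ratios) > 1.5

    def test_flag_reproducible_from_seed(self):
        a = generate_flag_pattern(np.random.default_rng(123)).pixels
        b = generate_flag_pattern(np.random.default_rng(123)).pixels
        np.testing.assert_array_equal(a, b)

    def test_surrogate_intensities_in_unit_range(self, rng):
        img = synthetic_natural_surrogate(rng).pixels
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_surrogate_orientation_energy_is_roughly_isotropic(self):
        rng = np.random.default_rng(21)
        tallies = np.zeros(4)
        for _ in range(40):
            e = _orientation_energy(synthetic_natural_surrogate(rng).pixels)
            tallies += np.array([e[0.0], e[45.0], e[90.0], e[135.0]])
        assert tallies.max() / tallies.min() <= 1.5

    def test_surrogates_from_different_seeds_are_decorrelated(self):
        a = synthetic_natural_surrogate(np.random.default_rng(1)).pixels.ravel()
        b = synthetic_natural_surrogate(np.random.default_rng(2)).pixels.ravel()
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.2
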