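"""Baseline removal, normalization, peak picking, alignment and denoising."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibermsi.core import IonImage, Spectrum, ValidationError
from fibermsi.preprocess import (PeakList, PreprocessConfig, align_peaks,
                                 denoise_ion_image, median_filter_image,
                                 pick_peaks, remove_baseline, rms_normalize)


def profile(mz, y):
    return Spectrum(np.asarray(mz, float), np.asarray(y, float), mode="profile")


class TestBaselineRemoval:
    def test_flat_spectrum_goes_to_zero(self):
        s = profile(np.linspace(100, 200, 101), np.full(101, 7.0))
        out = remove_baseline(s, window=11)
        np.testing.assert_allclose(out.intensity, 0.0)

    def test_narrow_peak_survives_within_one_percent(self):
        mz = np.linspace(100, 200, 1001)
        peak = 100 * np.exp(-0.5 * ((mz - 150) / 0.2) ** 2)
        out = remove_baseline(profile(mz, peak), window=51)
        assert out.intensity.max() == pytest.approx(100, rel=0.01)

    def test_ramp_plus_peak_removes_local_ramp(self):
        mz = np.linspace(100, 200, 1001)
        ramp = np.linspace(0, 50, 1001)
        peak = 100 * np.exp(-0.5 * ((mz - 150) / 0.2) ** 2)
        out = remove_baseline(profile(mz, ramp + peak), window=51)
        apex = np.argmax(peak)
        # apex after correction ~ original apex (ramp removed underneath)
        assert out.intensity[apex] == pytest.approx(100, rel=0.05)
        # away from the peak the ramp is gone
        assert out.intensity[:400].max() < 5

    def test_centroid_input_rejected(self):
        s = Spectrum([100.0, 200.0], [1.0, 2.0], mode="centroid")
        with pytest.raises(ValidationError, match="profile"):
            remove_baseline(s, 11)


class TestRMSNormalize:
    def test_hand_computed_example(self):
        s, factor = rms_normalize(profile([100, 200], [3.0, 4.0]))
        assert factor == pytest.approx(np.sqrt(12.5))
        np.testing.assert_allclose(s.intensity, [3 / np.sqrt(12.5),
                                                 4 / np.sqrt(12.5)])

    def test_constant_spectrum_becomes_ones(self):
        s, factor = rms_normalize(profile(np.arange(100, 110.0), np.full(10, 6.0)))
        assert factor == 6.0
        np.testing.assert_allclose(s.intensity, 1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError, match="all-zero"):
            rms_normalize(profile([100, 200], [0.0, 0.0]))

    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_output_rms_is_always_one(self, vals):
        vals = np.asarray(vals)
        if not np.any(vals > 0):
            return
        s, _ = rms_normalize(profile(np.arange(len(vals), dtype=float) + 100, vals))
        assert np.sqrt(np.mean(s.intensity ** 2)) == pytest.approx(1.0, rel=1e-9)


class TestPeakPicking:
    def test_flat_spectrum_has_no_peaks(self):
        assert len(pick_peaks(profile(np.arange(100.0, 200.0), np.full(100, 3.0)))) == 0

    def test_gaussian_peak_located_within_one_bin(self):
        rng = np.random.default_rng(42)
        mz = np.linspace(390, 410, 2001)  # bin width 0.01
        y = np.abs(rng.standard_normal(2001)) + \
            50 * np.exp(-0.5 * ((mz - 400.0) / 0.05) ** 2)
        pl = pick_peaks(profile(mz, y), snr_min=5.0)
        apex = pl.mz[np.argmax(pl.intensity)]
        assert abs(apex - 400.0) <= 0.01

    def test_pure_noise_yields_no_peaks_in_most_seeds(self):
        mz = np.linspace(100, 200, 500)
        n_with_peaks = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = np.clip(10 + rng.standard_normal(500), 0, None)
            if len(pick_peaks(profile(mz, y), snr_min=5.0)) > 0:
                n_with_peaks += 1
        assert n_with_peaks <= 5


class TestAlignment:
    def _pl(self, mzs, intensities=None):
        mzs = np.asarray(mzs, float)
        ints = np.ones_like(mzs) if intensities is None else np.asarray(intensities, float)
        return PeakList(mzs, ints, np.full(len(mzs), 10.0))

    def test_eight_ppm_apart_merges(self):
        pt = align_peaks([self._pl([500.000]), self._pl([500.004])],
                         [[0, 0], [1, 0]], tol_ppm=10, min_pixel_fraction=0)
        assert pt.n_features == 1
        assert 500.000 <= pt.feature_mz[0] <= 500.004  # within member span

    def test_twenty_ppm_apart_stays_separate(self):
        pt = align_peaks([self._pl([500.000]), self._pl([500.010])],
                         [[0, 0], [1, 0]], tol_ppm=10, min_pixel_fraction=0)
        assert pt.n_features == 2

    def test_identical_peaklists_reproduce_mz_exactly(self):
        shared = [200.0, 500.0, 900.0]
        pls = [self._pl(shared) for _ in range(4)]
        pt = align_peaks(pls, [[i, 0] for i in range(4)], tol_ppm=10,
                         min_pixel_fraction=0.5)
        np.testing.assert_array_equal(pt.feature_mz, shared)
        np.testing.assert_array_equal(pt.matrix, 1.0)

    def test_pixel_order_permutation_invariance(self):
        rng = np.random.default_rng(1)
        pls = [self._pl(np.sort(rng.choice(np.arange(100.0, 900.0, 1.0), 20,
                                           replace=False)),
                        rng.uniform(1, 5, 20)) for _ in range(6)]
        coords = [[i, 0] for i in range(6)]
        pt1 = align_peaks(pls, coords, tol_ppm=10, min_pixel_fraction=0)
        perm = [3, 1, 5, 0, 4, 2]
        pt2 = align_peaks([pls[i] for i in perm], [coords[i] for i in perm],
                          tol_ppm=10, min_pixel_fraction=0)
        np.testing.assert_allclose(pt1.feature_mz, pt2.feature_mz)
        # same pixel gets the same row regardless of input order
        inv = np.argsort(perm)
        np.testing.assert_allclose(pt1.matrix, pt2.matrix[:, inv])

    def test_min_pixel_fraction_drops_sparse_features(self):
        pls = [self._pl([500.0]), self._pl([500.0]), self._pl([700.0])]
        pt = align_peaks(pls, [[i, 0] for i in range(3)], tol_ppm=10,
                         min_pixel_fraction=0.5)
        np.testing.assert_array_equal(pt.feature_mz, [500.0])

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValidationError):
            align_peaks([self._pl([500.0])], [[0, 0]], tol_ppm=0)


class TestMedianFilter:
    def test_constant_image_unchanged(self):
        img = np.full((5, 7), 3.0)
        np.testing.assert_array_equal(median_filter_image(img, 3), img)

    def test_single_impulse_removed(self):
        img = np.full((5, 5), 2.0)
        img[2, 2] = 100.0
        out = median_filter_image(img, 3)
        assert out[2, 2] == 2.0

    def test_step_edge_preserved(self):
        img = np.ones((6, 8))
        img[:, 4:] = 5.0
        np.testing.assert_array_equal(median_filter_image(img, 3), img)

    def test_idempotent_on_piecewise_constant(self):
        img = np.ones((6, 8))
        img[:, 4:] = 5.0
        img[1, 1] = 9.0  # impulse removed by the first pass
        once = median_filter_image(img, 3)
        twice = median_filter_image(once, 3)
        np.testing.assert_array_equal(once, twice)

    def test_nan_pixels_stay_nan_and_do_not_leak(self):
        img = np.full((5, 5), 4.0)
        img[0, 0] = np.nan
        out = median_filter_image(img, 3)
        assert np.isnan(out[0, 0])
        assert np.all(out[~np.isnan(out)] == 4.0)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValidationError, match="odd"):
            denoise_ion_image(IonImage(np.ones((4, 4)), 500.0, 10.0), kernel=4)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"baseline_window": 2}, {"snr_min": 0}, {"align_tol_ppm": -1},
        {"min_pixel_fraction": 1.5}, {"median_kernel": 4},
    ])
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            PreprocessConfig(**kwargs)
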