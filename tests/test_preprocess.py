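"""Preprocessing: tissue detection, recalibration, smoothing, peak picking,
feature extraction — each checked against a direct oracle where one exists."""

import numpy as np
import pytest

from sccmsi import preprocess as pp
from sccmsi.msi_io import BACKGROUND, MsiDataset
from sccmsi.synthetic import SyntheticConfig, generate_dataset

from conftest import nearest_ppm


def make_dataset(spectra, coords=None):
    coords = coords if coords is not None else [(i, 0) for i in range(len(spectra))]
    return MsiDataset(
        coords=np.asarray(coords, int),
        mzs=[np.asarray(mz, float) for mz, _ in spectra],
        intensities=[np.asarray(it, float) for _, it in spectra],
    )


class TestTissueDetection:
    def test_exact_reference_centroid_flags_tissue(self):
        ds = make_dataset([([885.5493], [10.0]), ([400.0], [10.0])], coords=[(0, 0), (1, 0)])
        flags = pp.detect_tissue_pixels(ds)
        assert flags.tolist() == [True, False]

    def test_centroid_35_ppm_away_is_not_tissue(self):
        # 885.58 is ~35 ppm from 885.5493; tolerance is 30 ppm (~0.0266 Da)
        ds = make_dataset([([885.58], [10.0])])
        assert not pp.detect_tissue_pixels(ds).any()

    def test_zero_drift_synthetic_tissue_map_matches_truth(self):
        ds, _mask, truth = generate_dataset(SyntheticConfig(seed=2, drift_plane=(0, 0, 0)))
        flags = pp.detect_tissue_pixels(ds)
        expected = (truth.class_map != BACKGROUND)[ds.coords[:, 1], ds.coords[:, 0]]
        assert np.array_equal(flags, expected)


class TestRecalibration:
    def test_zero_drift_gives_near_zero_plane(self):
        ds, _m, _t = generate_dataset(SyntheticConfig(seed=1, drift_plane=(0.0, 0.0, 0.0)))
        model = pp.fit_recalibration(ds)
        h, w = ds.grid_shape
        corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]])
        assert np.all(np.abs(model.plane_ppm(corners[:, 0], corners[:, 1])) < 0.5)

    def test_planted_plane_recovered_within_half_ppm(self):
        plane = (0.1, -0.05, 5.0)
        ds, _m, _t = generate_dataset(SyntheticConfig(seed=4, drift_plane=plane))
        model = pp.fit_recalibration(ds)
        h, w = ds.grid_shape
        yy, xx = np.mgrid[0:h, 0:w]
        truth = plane[0] * xx + plane[1] * yy + plane[2]
        assert np.max(np.abs(model.plane_ppm(xx, yy) - truth)) < 0.5

    def test_pixels_without_refs_take_the_plane_value(self):
        ds, _m, _t = generate_dataset(SyntheticConfig(seed=5, grid_width=16, grid_height=16, n_peaks=40))
        flags = pp.detect_tissue_pixels(ds)
        victims = np.flatnonzero(flags)[:5]
        for i in victims:  # strip both reference ions from these pixels
            keep = np.ones(len(ds.mzs[i]), bool)
            for ref in (311.2950, 885.5493):
                keep &= np.abs(ds.mzs[i] - ref) / ref * 1e6 > 60
            ds.mzs[i] = ds.mzs[i][keep]
            ds.intensities[i] = ds.intensities[i][keep]
        model = pp.fit_recalibration(ds)
        for i in victims:
            x, y = ds.coords[i]
            assert model.per_pixel_ppm[i] == pytest.approx(float(model.plane_ppm(x, y)), abs=1e-9)
            assert not model.matched[i]

    def test_too_few_matches_raises_with_advice(self):
        ds = make_dataset([([400.0], [1.0]), ([500.0], [1.0]), ([600.0], [1.0])])
        with pytest.raises(pp.RecalibrationError, match="tol_ppm"):
            pp.fit_recalibration(ds)

    def test_apply_zero_model_is_identity(self):
        ds, _m, _t = generate_dataset(SyntheticConfig(seed=3, grid_width=8, grid_height=8, n_peaks=20))
        model = pp.RecalibrationModel(per_pixel_ppm=np.zeros(ds.n_pixels), plane=(0, 0, 0))
        cal = pp.apply_recalibration(ds, model)
        for a, b in zip(cal.mzs, ds.mzs):
            np.testing.assert_array_equal(a, b)

    def test_correction_reduces_ref_error_below_two_ppm(self, small, small_processed):
        cal = small_processed["cal"]
        flags = small_processed["flags"]
        errs = [
            nearest_ppm(mz, 885.5493)
            for mz, f in zip(cal.mzs, flags)
            if f
        ]
        assert np.median(errs) < 2.0

    def test_refitting_after_correction_finds_near_zero_plane(self, small_processed):
        model2 = pp.fit_recalibration(small_processed["cal"])
        assert np.all(np.abs(np.asarray(model2.plane) @ np.array([[31, 0, 1], [0, 31, 1], [0, 0, 1]]).T) < 0.5)


class TestMeanSpectrum:
    def test_single_pixel_reproduces_its_binned_spectrum(self):
        ds = make_dataset([([400.0, 500.0], [2.0, 6.0])])
        axis, mean = pp.mean_spectrum(ds, np.array([True]))
        idx = pp._axis_index(np.array([400.0, 500.0]), axis[0], 2.0, len(axis))
        assert mean[idx[0]] == 2.0 and mean[idx[1]] == 6.0
        assert mean.sum() == 8.0

    def test_two_pixels_average(self):
        ds = make_dataset([([500.0], [2.0]), ([500.0], [4.0])])
        _axis, mean = pp.mean_spectrum(ds, np.array([True, True]))
        assert mean.max() == pytest.approx(3.0)

    def test_matches_direct_loop_oracle_and_pixel_order_invariance(self):
        ds, _m, _t = generate_dataset(SyntheticConfig(seed=7, grid_width=8, grid_height=8, n_peaks=20))
        flags = pp.detect_tissue_pixels(ds)
        axis, mean = pp.mean_spectrum(ds, flags)
        # oracle: accumulate every centroid into its nearest bin by brute force
        expected = np.zeros(len(axis))
        for i in np.flatnonzero(flags):
            for mz, it in zip(ds.mzs[i], ds.intensities[i]):
                expected[np.argmin(np.abs(np.log(axis) - np.log(mz)))] += it
        expected /= flags.sum()
        np.testing.assert_allclose(mean, expected, rtol=1e-12)
        # permuting pixel order changes nothing
        perm = np.random.default_rng(0).permutation(ds.n_pixels)
        ds2 = MsiDataset(
            coords=ds.coords[perm],
            mzs=[ds.mzs[i] for i in perm],
            intensities=[ds.intensities[i] for i in perm],
        )
        _, mean2 = pp.mean_spectrum(ds2, flags[perm])
        np.testing.assert_allclose(mean2, mean, rtol=1e-12)

    def test_requires_a_tissue_pixel(self):
        ds = make_dataset([([500.0], [1.0])])
        with pytest.raises(ValueError):
            pp.mean_spectrum(ds, np.array([False]))


class TestSmoothing:
    def test_constant_signal_unchanged(self):
        out = pp.smooth_spectrum(np.full(100, 3.7))
        np.testing.assert_allclose(out, 3.7, rtol=1e-12)

    def test_quadratic_reproduced_exactly(self):
        t = np.linspace(0, 1, 200)
        y = 2.0 + 3.0 * t - 5.0 * t**2
        out = pp.smooth_spectrum(y, order=2, window=21)
        np.testing.assert_allclose(out, y, rtol=1e-9, atol=1e-9)

    def test_noise_suppression_on_gaussian_peak(self):
        rng = np.random.default_rng(42)
        t = np.arange(500)
        truth = np.exp(-0.5 * ((t - 250) / 30.0) ** 2)
        noisy = truth + rng.normal(0, 0.05, len(t))
        smoothed = pp.smooth_spectrum(noisy)
        assert np.sqrt(np.mean((smoothed - truth) ** 2)) < np.sqrt(np.mean((noisy - truth) ** 2))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            pp.smooth_spectrum(np.zeros(50), window=20)


class TestPeakPicking:
    def test_single_gaussian_centroid_within_5_ppm(self):
        axis = pp.make_mz_axis(300, 1000, 2.0)
        values = np.exp(-0.5 * ((np.log(axis / 500.0) * 1e6) / 6.0) ** 2)
        peaks = pp.pick_peaks(axis, values, min_rel_intensity=0.01)
        assert len(peaks) == 1
        assert abs(peaks.mzs[0] - 500.0) / 500.0 * 1e6 < 5.0

    def test_two_peaks_50_ppm_apart_both_kept(self):
        axis = pp.make_mz_axis(300, 1000, 2.0)
        ppm = np.log(axis / 500.0) * 1e6
        values = np.exp(-0.5 * (ppm / 4.0) ** 2) + 0.8 * np.exp(-0.5 * ((ppm - 50) / 4.0) ** 2)
        peaks = pp.pick_peaks(axis, values, min_rel_intensity=0.01, min_sep_ppm=20.0, window_ppm=10.0)
        assert len(peaks) == 2

    def test_flat_spectrum_yields_empty_list_with_warning(self):
        axis = pp.make_mz_axis(300, 1000, 2.0)
        with pytest.warns(UserWarning, match="flat"):
            peaks = pp.pick_peaks(axis, np.zeros(len(axis)))
        assert len(peaks) == 0

    def test_synthetic_mean_spectrum_recall_and_precision(self, small, small_processed):
        _ds, _mask, truth = small
        peaks = small_processed["peaks"]
        matched = [nearest_ppm(peaks.mzs, t) < 10.0 for t in truth.true_peak_mzs]
        assert np.mean(matched) >= 0.95
        spurious = [nearest_ppm(truth.true_peak_mzs, p) >= 10.0 for p in peaks.mzs]
        assert sum(spurious) == 0


class TestFeatureExtraction:
    def test_empty_window_gives_zero_and_single_centroid_its_intensity(self):
        ds = make_dataset([([500.0], [7.0])])
        peaks = pp.PeakList(mzs=np.array([400.0, 500.0]), window_ppm=10.0)
        fm = pp.extract_features(ds, peaks)
        np.testing.assert_array_equal(fm.values, [[0.0, 7.0]])

    def test_matches_nested_loop_oracle_on_small_grid(self):
        ds, _m, truth = generate_dataset(SyntheticConfig(seed=10, grid_width=8, grid_height=8, n_peaks=30))
        peaks = pp.PeakList(mzs=truth.true_peak_mzs, window_ppm=10.0)
        fm = pp.extract_features(ds, peaks)
        for i in range(ds.n_pixels):
            for j, p in enumerate(peaks.mzs):
                window = [
                    it
                    for mz, it in zip(ds.mzs[i], ds.intensities[i])
                    if abs(mz - p) / p * 1e6 <= 10.0 + 1e-9
                ]
                assert fm.values[i, j] == (max(window) if window else 0.0)

    def test_max_rule_when_multiple_centroids_share_a_window(self):
        ds = make_dataset([([499.999, 500.001], [3.0, 9.0])])
        fm = pp.extract_features(ds, pp.PeakList(mzs=np.array([500.0]), window_ppm=10.0))
        assert fm.values[0, 0] == 9.0


class TestPeakListInvariants:
    def test_nonascending_rejected(self):
        with pytest.raises(ValueError):
            pp.PeakList(mzs=np.array([500.0, 400.0]))

    def test_too_close_for_window_rejected(self):
        with pytest.raises(ValueError, match="window_ppm"):
            pp.PeakList(mzs=np.array([500.0, 500.005]), window_ppm=10.0)


def test_match_mz_three_ppm_tolerance():
    mzs = np.array([465.304, 885.5493])
    hits = pp.match_mz(mzs, np.array([465.3045, 885.56]), tol_ppm=3.0)
    assert hits[0] == 0  # ~1 ppm away: matched
    assert hits[1] == -1  # ~12 ppm away: not matched
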