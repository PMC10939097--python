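"""Domain-type invariants and file round trips for the core module."""

import numpy as np
import pytest

from fibermsi.core import (FeatureNotFoundError, ImzMLParseError, MetaboliteDB,
                           MSIDataset, PeakTable, ROILabelMap, Spectrum,
                           ValidationError, get_ion_image, read_gmt,
                           read_imzml, read_label_map, read_peaktable,
                           write_gmt, write_imzml, write_label_map,
                           write_peaktable)
from fibermsi.core import MetaboliteSetLibrary

import pandas as pd


class TestSpectrumInvariants:
    def test_rejects_unsorted_mz(self):
        with pytest.raises(ValidationError, match="strictly increasing"):
            Spectrum([200.0, 100.0], [1.0, 1.0])

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValidationError, match="lengths differ"):
            Spectrum([100.0, 200.0], [1.0])

    def test_rejects_negative_intensity(self):
        with pytest.raises(ValidationError, match="non-negative"):
            Spectrum([100.0, 200.0], [1.0, -0.5])


class TestDatasetInvariants:
    def test_rejects_duplicate_coords(self):
        s = Spectrum([100.0], [1.0], mode="centroid")
        with pytest.raises(ValidationError, match="duplicate"):
            MSIDataset([s, s], np.array([[0, 0], [0, 0]]))

    def test_rejects_nonpositive_pixel_size(self, small_dataset):
        with pytest.raises(ValidationError, match="pixel_size_um"):
            MSIDataset(small_dataset.spectra, small_dataset.coords,
                       pixel_size_um=0.0)

    def test_grid_shape_is_bounding_box(self, small_dataset):
        assert small_dataset.grid_shape == (2, 2)


class TestImzmlRoundTrip:
    def test_round_trip_preserves_data(self, tmp_path):
        from fibermsi.synthetic import make_phantom, simulate_msi

        truth = make_phantom(16, 16, layout="two_region", seed=5)
        (ds,), _ = simulate_msi(truth, n_features=10, n_marker_per_class=2,
                                seed=5)
        path = tmp_path / "phantom.imzML"
        write_imzml(ds, path)
        back = read_imzml(path)
        assert np.array_equal(back.coords, ds.coords)
        assert back.polarity == ds.polarity
        for a, b in zip(back.spectra, ds.spectra):
            np.testing.assert_allclose(a.mz, b.mz, rtol=0, atol=1e-9)
            # intensities stored as float32
            np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-6)

    def test_single_pixel_three_points(self, tmp_path):
        ds = MSIDataset([Spectrum([100.0, 200.0, 300.0], [1.0, 2.0, 3.0],
                                  mode="centroid")], np.array([[0, 0]]))
        path = tmp_path / "one.imzML"
        write_imzml(ds, path)
        back = read_imzml(path, mode="centroid")
        assert len(back) == 1 and len(back.spectra[0]) == 3

    def test_truncated_ibd_is_a_parse_error(self, tmp_path, small_dataset):
        path = tmp_path / "trunc.imzML"
        write_imzml(small_dataset, path)
        ibd = tmp_path / "trunc.ibd"
        ibd.write_bytes(ibd.read_bytes()[:20])
        with pytest.raises(ImzMLParseError):
            read_imzml(path)

    def test_missing_ibd_is_a_parse_error(self, tmp_path, small_dataset):
        path = tmp_path / "lost.imzML"
        write_imzml(small_dataset, path)
        (tmp_path / "lost.ibd").unlink()
        with pytest.raises(ImzMLParseError, match="ibd"):
            read_imzml(path)

    def test_refuses_empty_dataset(self, tmp_path):
        with pytest.raises(ValidationError):
            MSIDataset([], np.empty((0, 2)))


class TestIonImage:
    def test_eight_ppm_query_selects_feature(self, toy_peaktable):
        # 500.0040 is 8 ppm from the 500.0000 feature: within a 10 ppm window
        # the nearest feature is 500.004 itself (0 ppm); query between features
        img = get_ion_image(toy_peaktable, 500.0040, tol_ppm=10)
        assert img.feature_mz == pytest.approx(500.004)

    def test_out_of_tolerance_reports_nearest(self):
        pt = PeakTable(np.array([500.0]), np.ones((1, 1)), np.array([[0, 0]]))
        img = get_ion_image(pt, 500.0040, tol_ppm=10)  # 8 ppm away
        assert img.feature_mz == 500.0
        with pytest.raises(FeatureNotFoundError, match="nearest"):
            get_ion_image(pt, 500.0100, tol_ppm=10)  # 20 ppm away

    def test_exact_match_zero_ppm(self, toy_peaktable):
        img = get_ion_image(toy_peaktable, 800.0, tol_ppm=10)
        assert img.feature_mz == 800.0

    def test_unoccupied_pixels_are_nan(self):
        pt = PeakTable(np.array([500.0]), np.array([[2.0, 3.0]]),
                       np.array([[0, 0], [2, 1]]))
        img = get_ion_image(pt, 500.0, tol_ppm=10)
        assert img.values.shape == (2, 3)
        assert np.isnan(img.values[0, 1]) and img.values[0, 0] == 2.0


class TestLabelMaps:
    def test_csv_round_trip(self, tmp_path):
        roi = ROILabelMap(np.array([[0, 1], [2, 1]]), {1: "slow", 2: "fast"})
        p = write_label_map(roi, tmp_path / "roi.csv")
        back = read_label_map(p)
        assert np.array_equal(back.labels, roi.labels)

    def test_png_round_trip(self, tmp_path):
        roi = ROILabelMap(np.array([[0, 3], [2, 1]]))
        p = write_label_map(roi, tmp_path / "roi.png")
        back = read_label_map(p)
        assert np.array_equal(back.labels, roi.labels)

    def test_rejects_negative_labels(self):
        with pytest.raises(ValidationError):
            ROILabelMap(np.array([[-1, 0]]))


class TestSideTables:
    def test_gmt_round_trip(self, tmp_path):
        lib = MetaboliteSetLibrary({"acylcarnitines": ["ac1", "ac2"],
                                    "dipeptides": ["ans", "car"]})
        p = write_gmt(lib, tmp_path / "sets.gmt")
        back = read_gmt(p)
        assert back.sets == lib.sets

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            MetaboliteSetLibrary({"bad": []})

    def test_duplicate_metabolite_ids_rejected(self):
        t = pd.DataFrame({"id": ["a", "a"], "name": ["x", "y"],
                          "neutral_mass": [100.0, 200.0]})
        with pytest.raises(ValidationError, match="duplicate"):
            MetaboliteDB(t)

    def test_peaktable_csv_round_trip(self, tmp_path, toy_peaktable):
        p = write_peaktable(toy_peaktable, tmp_path / "pt.csv")
        back = read_peaktable(p)
        np.testing.assert_allclose(back.feature_mz, toy_peaktable.feature_mz)
        np.testing.assert_allclose(back.matrix, toy_peaktable.matrix)
        assert np.array_equal(back.coords, toy_peaktable.coords)
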