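"""HU conversion, binning and smoothing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from ntra import PixelSet, build_histogram, ct_to_hu, smooth_histogram
from ntra.radiodensity import HU_INTERCEPT, HU_SLOPE, read_pixel_csv, write_histogram_csv


class TestCtToHu:
    @pytest.mark.parametrize(
        "ct, hu",
        [
            (0.0, -190.0),                 # intercept alone
            (190.0 / 2.26625, 0.0),        # the root of the transform
            (100.0, 36.625),
        ],
    )
    def test_pointwise(self, ct, hu):
        assert ct_to_hu([ct])[0] == pytest.approx(hu, abs=1e-9)

    def test_order_preserved(self):
        out = ct_to_hu([3.0, 1.0, 2.0])
        assert np.all(np.argsort(out) == np.argsort([3.0, 1.0, 2.0]))

    def test_nonfinite_rejected_with_index(self):
        with pytest.raises(ValueError, match="index 2"):
            ct_to_hu([1.0, 2.0, np.nan, 4.0])

    @given(
        v=hnp.arrays(np.float64, 5, elements=st.floats(-1e3, 1e3)),
        a=st.floats(-10, 10),
        b=st.floats(-100, 100),
    )
    def test_affine_property(self, v, a, b):
        """The transform is affine: scaling inputs scales the linear part."""
        got = ct_to_hu(a * v + b)
        expected = a * HU_SLOPE * v + (HU_SLOPE * b + HU_INTERCEPT)
        np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-9)


class TestBuildHistogram:
    def test_point_mass(self):
        p = PixelSet("s", np.zeros(1000))
        h = build_histogram(p)
        assert h.counts.max() == 1000
        assert np.count_nonzero(h.counts) == 1
        assert h.n_out_of_range == 0

    def test_out_of_range_bookkeeping(self):
        p = PixelSet("s", np.array([-250.0, 0.0, 250.0]))
        h = build_histogram(p)
        assert h.counts.sum() == 1
        assert h.n_below_range == 1 and h.n_above_range == 1
        assert h.counts.sum() + h.n_out_of_range == h.total_pixels

    def test_uniform_counts_binomial(self):
        """Uniform sampling fills bins to n/128 within 5 sigma."""
        n = 128 * 2000
        rng = np.random.default_rng(0)
        p = PixelSet("s", rng.uniform(-200, 200, n))
        h = build_histogram(p)
        expect = n / 128
        sigma = np.sqrt(n * (1 / 128) * (1 - 1 / 128))
        assert np.all(np.abs(h.counts - expect) < 5 * sigma)

    def test_half_open_bins_last_closed(self):
        # an interior edge value belongs to the right bin; the top edge
        # is included in the last bin
        edges_val = -200 + 400 / 128  # first interior edge
        p = PixelSet("s", np.array([edges_val, 200.0]))
        h = build_histogram(p)
        assert h.counts[1] == 1 and h.counts[-1] == 1

    def test_ct_number_input_transformed_once(self):
        raw = np.array([100.0, 0.0])
        h = build_histogram(PixelSet("s", raw, unit="ct_number"))
        direct = build_histogram(PixelSet("s", ct_to_hu(raw)))
        np.testing.assert_array_equal(h.counts, direct.counts)

    def test_rejections(self):
        with pytest.raises(ValueError, match="empty"):
            build_histogram(PixelSet("s", np.array([])))
        with pytest.raises(ValueError, match="inverted"):
            build_histogram(PixelSet("s", np.array([0.0])), hu_range=(200, -200))
        with pytest.raises(ValueError):
            build_histogram(PixelSet("s", np.array([0.0])), n_bins=4)

    @given(hnp.arrays(np.float64, st.integers(1, 300), elements=st.floats(-500, 500)))
    def test_mass_conservation(self, values):
        h = build_histogram(PixelSet("s", values))
        assert h.counts.sum() + h.n_out_of_range == values.size


class TestSmoothing:
    def test_integral_unit(self, trimodal_hist):
        area = np.trapezoid(trimodal_hist.density, trimodal_hist.bin_centers)
        assert area == pytest.approx(1.0, rel=1e-3)

    def test_count_mode_integral(self, trimodal_pixels):
        h = smooth_histogram(build_histogram(trimodal_pixels), normalize=False)
        area = np.trapezoid(h.density, h.bin_centers)
        assert area == pytest.approx(h.counts.sum(), rel=1e-3)

    def test_impulse_response_is_kernel(self):
        p = PixelSet("s", np.zeros(500))
        h = smooth_histogram(build_histogram(p), bandwidth=10.0)
        peak = int(np.argmax(h.density))
        # symmetric Gaussian bump around the impulse bin
        assert h.bin_centers[peak] == pytest.approx(0.0, abs=h.bin_width)
        left = h.density[peak - 5: peak]
        right = h.density[peak + 1: peak + 6][::-1]
        np.testing.assert_allclose(left, right, rtol=1e-6)

    def test_zero_bandwidth_limit(self, trimodal_pixels):
        h0 = build_histogram(trimodal_pixels)
        h = smooth_histogram(h0, bandwidth=1e-9)
        expected = h0.counts / (h0.counts.sum() * h0.bin_width)
        np.testing.assert_allclose(h.density, expected, rtol=1e-6)

    def test_rejections(self, trimodal_pixels):
        h = build_histogram(trimodal_pixels)
        with pytest.raises(ValueError, match="bandwidth"):
            smooth_histogram(h, bandwidth=-1.0)

    def test_nonnegative(self, trimodal_hist):
        assert np.all(trimodal_hist.density >= 0)


class TestIO:
    def test_pixel_roundtrip(self, tmp_path):
        path = tmp_path / "S1.csv"
        np.savetxt(path, [1.5, -2.5, 30.0])
        p = read_pixel_csv(path)
        assert p.subject_id == "S1"
        np.testing.assert_allclose(p.values, [1.5, -2.5, 30.0])

    def test_histogram_csv(self, tmp_path, trimodal_hist):
        path = tmp_path / "h.csv"
        write_histogram_csv(trimodal_hist, path)
        header = path.read_text().splitlines()[0]
        assert header == "bin_left,bin_right,bin_center,count,density"
        assert len(path.read_text().splitlines()) == 129

    def test_dicom_rescale_fields(self, tmp_path):
        pydicom = pytest.importorskip("pydicom")
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = SecondaryCaptureImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Rows = ds.Columns = 4
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = 2.0
        ds.RescaleIntercept = -100.0
        arr = np.arange(16, dtype=np.uint16).reshape(4, 4)
        ds.PixelData = arr.tobytes()
        path = tmp_path / "slice.dcm"
        ds.save_as(path, enforce_file_format=True)

        from ntra.radiodensity import read_dicom_pixels

        mask = np.zeros((4, 4), dtype=bool)
        mask[0, :2] = True
        p = read_dicom_pixels(path, mask=mask)
        np.testing.assert_allclose(p.values, [0 * 2 - 100, 1 * 2 - 100])
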