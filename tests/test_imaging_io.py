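"""Round-trips and validation for NIfTI, DICOM series and PNG masks."""

import numpy as np
import pydicom
import pytest
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from sedseg.imaging_io import (CTVolume, FormatError, LabelValidationError,
                               LabelVolume, read_labels, read_mask_png,
                               read_volume, write_labels, write_mask_png,
                               write_volume)


class TestNifti:
    def test_volume_round_trip(self, tmp_path, rng):
        vox = rng.normal(0, 200, size=(3, 16, 16)).astype(np.float32)
        vol = CTVolume(vox, spacing=(2.5, 0.7, 0.7), identifier="case0")
        path = tmp_path / "vol.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_allclose(back.voxels, vox, atol=1e-4)
        assert back.spacing == pytest.approx(vol.spacing)

    def test_single_slice_round_trip(self, tmp_path):
        vox = np.arange(64, dtype=np.float32).reshape(1, 8, 8)
        path = tmp_path / "one.nii"
        write_volume(CTVolume(vox), path)
        np.testing.assert_allclose(read_volume(path).voxels, vox, atol=1e-5)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "absent.nii")


class TestLabels:
    def test_full_range_round_trip(self, tmp_path, rng):
        lab = rng.integers(0, 3, size=(4, 8, 8)).astype(np.uint8)
        path = tmp_path / "lab.nii.gz"
        write_labels(LabelVolume(lab, spacing=(1, 1, 1)), path)
        back = read_labels(path)
        np.testing.assert_array_equal(back.labels, lab)

    def test_all_zero_is_valid_with_empty_liver(self):
        lv = LabelVolume(np.zeros((2, 4, 4), dtype=np.uint8))
        assert not lv.liver_mask.any() and not lv.tumor_mask.any()

    def test_out_of_range_label_rejected(self):
        arr = np.zeros((1, 4, 4), dtype=np.uint8)
        arr[0, 0, 0] = 3
        with pytest.raises(LabelValidationError, match="3"):
            LabelVolume(arr)

    def test_non_integral_rejected(self):
        with pytest.raises(LabelValidationError):
            LabelVolume(np.full((1, 2, 2), 0.5))

    def test_liver_contains_tumor(self, rng):
        lab = rng.integers(0, 3, size=(3, 8, 8))
        lv = LabelVolume(lab)
        assert np.all(lv.liver_mask[lv.tumor_mask])


def _dicom_slice(path, z, rows=8, cols=8, value=1024, slope=1.0, intercept=-1024.0):
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = generate_uid()
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.Rows, ds.Columns = rows, cols
    ds.BitsAllocated = ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    ds.PixelSpacing = [0.8, 0.8]
    ds.SliceThickness = 1.0
    ds.ImagePositionPatient = [0.0, 0.0, float(z)]
    ds.InstanceNumber = z + 1
    ds.PixelData = np.full((rows, cols), value, dtype=np.uint16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


class TestDicomSeries:
    def test_rescale_to_hu_and_spacing(self, tmp_path):
        series = tmp_path / "series"
        series.mkdir()
        for z in range(3):
            _dicom_slice(series / f"s{z}.dcm", z)
        vol = read_volume(series, format="dicom_series")
        # stored 1024 with slope 1, intercept -1024 -> HU 0
        np.testing.assert_allclose(vol.voxels, 0.0)
        assert vol.voxels.shape == (3, 8, 8)
        assert vol.spacing == pytest.approx((1.0, 0.8, 0.8))

    def test_inconsistent_geometry_rejected(self, tmp_path):
        series = tmp_path / "series"
        series.mkdir()
        _dicom_slice(series / "a.dcm", 0, rows=8)
        _dicom_slice(series / "b.dcm", 1, rows=16)
        with pytest.raises(FormatError, match="inconsistent"):
            read_volume(series, format="dicom_series")

    def test_empty_directory(self, tmp_path):
        empty = tmp_path / "empty"
        empty.mkdir()
        with pytest.raises(FileNotFoundError):
            read_volume(empty, format="dicom_series")


class TestMaskPng:
    @pytest.mark.parametrize("name", ["checkerboard", "empty", "disk"])
    def test_lossless_round_trip(self, tmp_path, name):
        if name == "checkerboard":
            mask = np.indices((32, 32)).sum(axis=0) % 2 == 0
        elif name == "empty":
            mask = np.zeros((32, 32), dtype=bool)
        else:
            yy, xx = np.mgrid[0:256, 0:256]
            mask = (yy - 128) ** 2 + (xx - 128) ** 2 <= 64 ** 2
        path = tmp_path / f"{name}.png"
        write_mask_png(mask, path)
        np.testing.assert_array_equal(read_mask_png(path), mask)

    def test_non_binary_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_mask_png(np.full((4, 4), 2), tmp_path / "x.png")


class TestCTVolumeValidation:
    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            CTVolume(np.zeros((1, 4, 4)), spacing=(0.0, 1.0, 1.0))

    def test_2d_grid_rejected(self):
        with pytest.raises(ValueError):
            CTVolume(np.zeros((4, 4)))
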