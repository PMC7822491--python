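"""Reading and writing the medical-imaging formats the pipeline touches.

Volumes are held as :class:`CTVolume` — a (slice, row, col) grid of
Hounsfield units with millimetre spacing and a 4x4 voxel-to-world affine.
Paired ground truth lives in :class:`LabelVolume` with the LiTS label
convention: 0 background, 1 liver, 2 tumor; the liver mask is
``labels >= 1`` so it always contains the tumor mask.

NIfTI I/O goes through nibabel (which stores grids as (col, row, slice);
the transpose is handled here), DICOM series through pydicom with the
header's rescale slope/intercept applied, and 2-D masks round-trip as
8-bit 0/255 PNGs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from PIL import Image

__all__ = [
    "CTVolume",
    "LabelVolume",
    "FormatError",
    "LabelValidationError",
    "read_volume",
    "read_labels",
    "write_volume",
    "write_labels",
    "write_mask_png",
    "read_mask_png",
]


class FormatError(ValueError):
    """The file(s) do not parse as the named format."""


class LabelValidationError(ValueError):
    """Label values outside the {0, 1, 2} convention."""


def _default_affine(spacing) -> np.ndarray:
    # world = diag(col_mm, row_mm, slice_mm) @ (col, row, slice) index
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing[2], spacing[1], spacing[0]
    return aff


@dataclass
class CTVolume:
    """A 3-D CT grid in Hounsfield units.

    ``voxels`` is (slices, rows, cols); ``spacing`` is
    (slice_mm, row_mm, col_mm); ``affine`` maps (col, row, slice, 1)
    voxel indices to world millimetres (nibabel convention).
    """

    voxels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = None  # type: ignore[assignment]
    identifier: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("voxels must be a 3-D grid with >= 1 slice")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive millimetre values")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class LabelVolume:
    """Liver/tumor ground truth on the LiTS {0, 1, 2} convention."""

    labels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = None  # type: ignore[assignment]
    identifier: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise LabelValidationError("labels must be integral")
            arr = arr.astype(np.int16)
        if arr.ndim != 3:
            raise ValueError("labels must be a 3-D grid")
        bad = np.setdiff1d(np.unique(arr), [0, 1, 2])
        if bad.size:
            raise LabelValidationError(
                f"labels outside {{0, 1, 2}}: found {bad.tolist()}"
            )
        self.labels = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive millimetre values")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def liver_mask(self) -> np.ndarray:
        return self.labels >= 1

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.labels == 2


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _read_nifti(path: Path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)  # slope/intercept applied by nibabel
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D NIfTI, got {data.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    # nibabel grid is (col, row, slice) -> internal (slice, row, col)
    return data.T, (float(zooms[2]), float(zooms[1]), float(zooms[0])), img.affine


def read_volume(path, format: str | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    HU values are returned as stored, beyond applying the format's own
    rescale slope/intercept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "nifti":
        data, spacing, affine = _read_nifti(path)
        return CTVolume(data, spacing, affine, identifier=path.stem.split(".")[0])
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def read_labels(path) -> LabelVolume:
    """Read a label volume; values must be integers in {0, 1, 2}."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such label file: {path}")
    data, spacing, affine = _read_nifti(path)
    return LabelVolume(data, spacing, affine, identifier=path.stem.split(".")[0])


def write_volume(volume: CTVolume, path) -> None:
    img = nib.Nifti1Image(volume.voxels.T.astype(np.float32), volume.affine)
    img.header.set_zooms((volume.spacing[2], volume.spacing[1], volume.spacing[0]))
    nib.save(img, str(path))


def write_labels(labels: LabelVolume, path) -> None:
    img = nib.Nifti1Image(labels.labels.T.astype(np.uint8), labels.affine)
    img.header.set_zooms((labels.spacing[2], labels.spacing[1], labels.spacing[0]))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _read_dicom_series(directory: Path) -> CTVolume:
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FileNotFoundError(f"no .dcm files in {directory}")
    slices = []
    for f in files:
        try:
            slices.append(pydicom.dcmread(str(f)))
        except Exception as exc:  # pydicom raises several error types
            raise FormatError(f"{f}: not a readable DICOM file ({exc})") from exc

    def z_of(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=z_of)
    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in slices}
    if len(shapes) != 1:
        raise FormatError(f"inconsistent slice shapes in series: {sorted(shapes)}")

    hu = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    voxels = np.stack(hu, axis=0)

    ps = getattr(slices[0], "PixelSpacing", [1.0, 1.0])
    if len(slices) > 1 and hasattr(slices[0], "ImagePositionPatient"):
        dz = [z_of(b) - z_of(a) for a, b in zip(slices, slices[1:])]
        if max(dz) - min(dz) > 1e-3:
            raise FormatError("inconsistent slice spacing in series")
        slice_mm = float(dz[0])
    else:
        slice_mm = float(getattr(slices[0], "SliceThickness", 1.0))
    spacing = (slice_mm, float(ps[0]), float(ps[1]))
    return CTVolume(voxels, spacing, identifier=directory.name)


# ---------------------------------------------------------------------------
# PNG masks
# ---------------------------------------------------------------------------

def write_mask_png(mask: np.ndarray, path) -> None:
    """Write a 2-D binary mask as an 8-bit 0/255 PNG (lossless)."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if mask.dtype != bool and not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(str(path))


def read_mask_png(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask: {path}")
    arr = np.asarray(Image.open(str(path)).convert("L"))
    return arr >= 128
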