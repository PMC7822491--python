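"""Hounsfield-unit windowing, resizing and dataset splitting.

Raw CT voxels are clipped to a soft-tissue window (default [-100, 200]
HU), affinely rescaled to [0, 1], and downscaled to the fixed network
resolution (default 256x256, bilinear for images, nearest-neighbour for
masks so they stay binary).  Slices become :class:`SliceSample` records
carrying their provenance, and :func:`split_dataset` performs the
train / validation / test partition with a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .imaging_io import CTVolume, LabelVolume

__all__ = [
    "SliceSample",
    "DatasetSplit",
    "truncate_hu",
    "normalize",
    "resize_to",
    "volume_to_slices",
    "split_dataset",
]

HU_LOW_DEFAULT = -100.0
HU_HIGH_DEFAULT = 200.0
TARGET_SIZE_DEFAULT = 256


@dataclass
class SliceSample:
    """One preprocessed 2-D training/testing sample.

    ``image`` is in [0, 1]; the optional masks are boolean arrays of the
    same shape with ``tumor_mask`` nested in ``liver_mask``.
    """

    image: np.ndarray
    liver_mask: np.ndarray | None = None
    tumor_mask: np.ndarray | None = None
    provenance: tuple = ("", -1)  # (case id, slice index)

    def __post_init__(self) -> None:
        if self.image.ndim != 2:
            raise ValueError("image must be 2-D")
        if self.image.size and (self.image.min() < 0.0 or self.image.max() > 1.0):
            raise ValueError("image values must lie in [0, 1]")
        for m in (self.liver_mask, self.tumor_mask):
            if m is not None and m.shape != self.image.shape:
                raise ValueError("mask shape must match image shape")
        if self.liver_mask is not None and self.tumor_mask is not None:
            if np.any(self.tumor_mask & ~self.liver_mask):
                raise ValueError("tumor mask must be contained in liver mask")

    @property
    def has_liver(self) -> bool:
        return self.liver_mask is not None and bool(self.liver_mask.any())


@dataclass
class DatasetSplit:
    """Disjoint, exhaustive train/validation/test partition."""

    train: list
    validation: list
    test: list

    def __post_init__(self) -> None:
        ids = [id(s) for part in (self.train, self.validation, self.test) for s in part]
        if len(ids) != len(set(ids)):
            raise ValueError("split parts must be disjoint")


def truncate_hu(image: np.ndarray, low: float = HU_LOW_DEFAULT,
                high: float = HU_HIGH_DEFAULT) -> np.ndarray:
    """Clip HU values to the window [low, high] (monotone, idempotent)."""
    if low >= high:
        raise ValueError(f"invalid window: low {low} must be < high {high}")
    return np.clip(np.asarray(image, dtype=float), low, high)


def normalize(image: np.ndarray, low: float = HU_LOW_DEFAULT,
              high: float = HU_HIGH_DEFAULT) -> np.ndarray:
    """Affinely map a truncated image from [low, high] onto [0, 1]."""
    if low >= high:
        raise ValueError(f"invalid window: low {low} must be < high {high}")
    image = np.asarray(image, dtype=float)
    if image.size and (image.min() < low or image.max() > high):
        raise ValueError("normalize expects an already-truncated image")
    return (image - low) / (high - low)


def resize_to(image: np.ndarray, size: int = TARGET_SIZE_DEFAULT,
              is_mask: bool = False) -> np.ndarray:
    """Resample to ``size x size``: bilinear for images, nearest for masks."""
    image = np.asarray(image)
    if image.ndim != 2 or 0 in image.shape:
        raise ValueError("expected a non-empty 2-D grid")
    if image.shape == (size, size):
        return image.astype(bool) if is_mask else image.astype(float)
    if is_mask:
        out = _sk_resize(image.astype(float), (size, size), order=0,
                         anti_aliasing=False, preserve_range=True)
        return out > 0.5
    out = _sk_resize(image.astype(float), (size, size), order=1,
                     anti_aliasing=image.shape[0] > size, preserve_range=True)
    return out


def volume_to_slices(volume: CTVolume, labels: LabelVolume | None = None,
                     hu_low: float = HU_LOW_DEFAULT, hu_high: float = HU_HIGH_DEFAULT,
                     target_size: int = TARGET_SIZE_DEFAULT) -> list:
    """Window, normalize and resize every axial slice of a volume."""
    if labels is not None and labels.labels.shape != volume.voxels.shape:
        raise ValueError("label grid must match the CT grid")
    samples = []
    for z in range(volume.voxels.shape[0]):
        img = normalize(truncate_hu(volume.voxels[z], hu_low, hu_high), hu_low, hu_high)
        img = np.clip(resize_to(img, target_size), 0.0, 1.0)
        liver = tumor = None
        if labels is not None:
            liver = resize_to(labels.liver_mask[z], target_size, is_mask=True)
            tumor = resize_to(labels.tumor_mask[z], target_size, is_mask=True)
        samples.append(SliceSample(image=img, liver_mask=liver, tumor_mask=tumor,
                                   provenance=(volume.identifier, z)))
    return samples


def split_dataset(samples: Sequence, n_test: int, val_fraction: float = 0.2,
                  seed: int = 0) -> DatasetSplit:
    """Randomly partition ``samples`` into train / validation / test.

    ``n_test`` samples form the test set; ``val_fraction`` of the
    remaining pool (rounded down) becomes validation.  Reproducible under
    a fixed seed.
    """
    n = len(samples)
    if not 0 <= n_test < n:
        raise ValueError(f"n_test={n_test} must satisfy 0 <= n_test < {n}")
    if not 0.0 <= val_fraction < 1.0:
        raise ValueError("val_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = perm[:n_test]
    pool = perm[n_test:]
    n_val = int(val_fraction * len(pool))
    return DatasetSplit(
        train=[samples[i] for i in pool[n_val:]],
        validation=[samples[i] for i in pool[:n_val]],
        test=[samples[i] for i in test_idx],
    )
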