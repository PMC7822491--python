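"""Two-stage inference: liver localization, mask multiplication, tumor
extraction.

Stage 1 predicts a liver probability map and thresholds it into a liver
mask; the input image is multiplied elementwise by that mask, so stage 2
sees only liver tissue; stage 2's thresholded output is intersected with
the liver mask, guaranteeing ``tumor_mask ⊆ liver_mask``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import CTVolume, LabelVolume
from .nn import GraphModel
from .preprocess import resize_to, volume_to_slices

__all__ = ["CascadeResult", "run_cascade", "run_cascade_volume"]

DEFAULT_THRESHOLD = 0.5


@dataclass
class CascadeResult:
    """Per-slice output of the two-stage pipeline."""

    liver_prob: np.ndarray
    liver_mask: np.ndarray
    liver_image: np.ndarray
    tumor_prob: np.ndarray
    tumor_mask: np.ndarray


def _predict(model: GraphModel, images: np.ndarray) -> np.ndarray:
    """Batched inference; ``images`` is (N, H, W) in [0, 1]."""
    out = np.empty_like(images, dtype=np.float32)
    for i in range(0, len(images), 8):
        chunk = images[i : i + 8, :, :, None].astype(np.float32)
        out[i : i + 8] = model.forward(chunk, train=False)[..., 0]
    return out


def run_cascade(image: np.ndarray, sed1: GraphModel, sed2: GraphModel,
                threshold: float = DEFAULT_THRESHOLD) -> CascadeResult:
    """Run both stages on one preprocessed slice in [0, 1]."""
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError("expected a single 2-D slice")
    liver_prob = _predict(sed1, image[None])[0]
    liver_mask = liver_prob >= threshold
    liver_image = image * liver_mask
    tumor_prob = _predict(sed2, liver_image[None])[0]
    tumor_mask = (tumor_prob >= threshold) & liver_mask
    return CascadeResult(liver_prob, liver_mask, liver_image, tumor_prob, tumor_mask)


def run_cascade_volume(volume: CTVolume, sed1: GraphModel, sed2: GraphModel,
                       threshold: float = DEFAULT_THRESHOLD,
                       hu_low: float = -100.0, hu_high: float = 200.0):
    """Slice-wise cascade over a CT volume.

    Slices are windowed/normalized/resized to the stage-1 input size, run
    through both stages in index order, and the per-slice masks are
    resampled back to the original grid and reassembled into a
    :class:`LabelVolume` on the {0, 1, 2} convention.
    Returns ``(results, label_volume)``.
    """
    if volume.voxels.shape[0] < 1 or volume.voxels[0].size == 0:
        raise ValueError("empty volume")
    target = sed1.input_size[0]
    samples = volume_to_slices(volume, None, hu_low, hu_high, target_size=target)
    images = np.stack([s.image for s in samples]).astype(np.float32)

    liver_prob = _predict(sed1, images)
    liver_mask = liver_prob >= threshold
    liver_images = images * liver_mask
    tumor_prob = _predict(sed2, liver_images)
    tumor_mask = (tumor_prob >= threshold) & liver_mask

    results = [
        CascadeResult(liver_prob[z], liver_mask[z], liver_images[z],
                      tumor_prob[z], tumor_mask[z])
        for z in range(len(samples))
    ]

    out = np.zeros(volume.voxels.shape, dtype=np.uint8)
    orig = volume.voxels.shape[1]
    for z, r in enumerate(results):
        liv = resize_to(r.liver_mask, orig, is_mask=True)
        tum = resize_to(r.tumor_mask, orig, is_mask=True)
        out[z][liv] = 1
        out[z][tum & liv] = 2
    labels = LabelVolume(out, volume.spacing, volume.affine,
                         identifier=volume.identifier)
    return results, labels
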