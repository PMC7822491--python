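"""Synthetic abdominal CT phantoms with liver and tumor ground truth.

Each phantom volume mimics the structure of a liver-CT benchmark case:
a soft-tissue body oval on an air background, one smooth liver-like
region per slice (a randomized, radially perturbed ellipse that deforms
coherently across slices), zero or more hypodense tumor blobs strictly
inside the liver, a few distractor organs of liver-like intensity
outside it, and additive Gaussian HU noise.  Labels follow the LiTS
convention (0 background, 1 liver, 2 tumor), so the tumor mask is nested
in the liver mask by construction.

Default intensities put tumors (20-60 HU) below liver parenchyma
(70-140 HU) while distractor tissue overlaps the liver range, so the
stage-1 network cannot solve the task by thresholding alone and the
stage-2 network sees realistically modest lesion contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging_io import CTVolume, LabelVolume

__all__ = ["PhantomConfig", "PhantomError", "generate_volume", "generate_dataset"]


class PhantomError(RuntimeError):
    """Phantom construction failed (e.g. a tumor cannot fit in the liver)."""


@dataclass
class PhantomConfig:
    """Parameters of the synthetic CT generator.

    HU ranges are (low, high) with tumors darker than liver (hypodense
    lesions).  ``tumor_radius_range`` is in pixels of the configured grid.
    """

    grid: tuple = (512, 512)
    n_slices: int = 16
    liver_hu: tuple = (70.0, 140.0)
    tumor_hu: tuple = (20.0, 60.0)
    body_hu: tuple = (-20.0, 40.0)
    distractor_hu: tuple = (60.0, 120.0)
    background_hu: float = -1000.0
    n_distractors: int = 3
    noise_sd: float = 10.0
    tumor_count_range: tuple = (0, 3)
    tumor_radius_range: tuple = None  # type: ignore[assignment]
    spacing: tuple = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("liver_hu", "tumor_hu", "body_hu", "distractor_hu"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValueError(f"{name} must be an ordered (low, high) range")
        if self.tumor_hu[1] > self.liver_hu[0] + (self.liver_hu[1] - self.liver_hu[0]):
            pass  # overlap allowed; hard error only if inverted
        if self.tumor_hu[0] >= self.liver_hu[1]:
            raise ValueError("tumors must be hypodense relative to the liver")
        if self.tumor_radius_range is None:
            scale = min(self.grid) / 512.0
            self.tumor_radius_range = (max(3.0, 12.0 * scale), max(5.0, 45.0 * scale))
        lo, hi = self.tumor_radius_range
        if lo <= 0 or lo > hi:
            raise ValueError("tumor_radius_range must be positive and ordered")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")


def _smooth_field(rng, shape, amplitude, sigma=24.0):
    """Zero-mean smooth random field bounded by +-amplitude."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    peak = np.abs(f).max()
    if peak == 0:
        return np.zeros(shape)
    return f / peak * amplitude


def _blob_mask(shape, center, axes, angle, wobble):
    """Radially perturbed ellipse: rho(theta) <= 1 + sum_m c_m cos(m theta + phi)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dc + sa * dr) / axes[1]
    v = (-sa * dc + ca * dr) / axes[0]
    rho = np.sqrt(u * u + v * v)
    theta = np.arctan2(v, u)
    bound = np.ones_like(theta)
    for m, (c_m, phi_m) in wobble.items():
        bound = bound + c_m * np.cos(m * theta + phi_m)
    return rho <= bound


def _draw_range(rng, hu_range, shape, field_sigma=24.0):
    """Intensities guaranteed inside ``hu_range``: per-region base level in
    the central part of the range plus a bounded smooth variation."""
    lo, hi = hu_range
    span = hi - lo
    base = rng.uniform(lo + 0.3 * span, hi - 0.3 * span)
    return base + _smooth_field(rng, shape, 0.3 * span, sigma=field_sigma)


def generate_volume(config: PhantomConfig):
    """Generate one phantom; returns ``(CTVolume, LabelVolume)``.

    Deterministic under a fixed ``config.seed``.  Raises
    :class:`PhantomError` if a sampled tumor cannot be placed strictly
    inside the liver after a bounded number of attempts.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.grid
    n = cfg.n_slices
    ident = f"phantom-{cfg.seed:06d}"

    hu = np.full((n, h, w), cfg.background_hu, dtype=float)
    labels = np.zeros((n, h, w), dtype=np.uint8)

    # body oval, fixed across slices
    body_center = (h * 0.5 + rng.uniform(-0.03, 0.03) * h,
                   w * 0.5 + rng.uniform(-0.03, 0.03) * w)
    body_axes = (h * rng.uniform(0.36, 0.42), w * rng.uniform(0.40, 0.46))
    body = _blob_mask((h, w), body_center, body_axes, 0.0, {})

    # liver base shape, deformed coherently along the stack
    liver_center = (body_center[0] + rng.uniform(-0.08, 0.0) * h,
                    body_center[1] + rng.uniform(-0.18, -0.05) * w)
    liver_axes = (h * rng.uniform(0.16, 0.22), w * rng.uniform(0.18, 0.26))
    liver_angle = rng.uniform(-0.5, 0.5)
    wobble = {m: (rng.uniform(0.02, 0.07), rng.uniform(0, 2 * np.pi))
              for m in (2, 3, 4)}
    # through-stack size profile: largest mid-stack, never vanishing
    zz = (np.arange(n) + 0.5) / n
    profile = 0.75 + 0.25 * np.sin(np.pi * np.clip(zz, 0.04, 0.96))
    drift = rng.uniform(-1.5, 1.5, size=2)

    liver_masks = []
    for z in range(n):
        c = (liver_center[0] + drift[0] * (z - n / 2),
             liver_center[1] + drift[1] * (z - n / 2))
        ax = (liver_axes[0] * profile[z], liver_axes[1] * profile[z])
        m = _blob_mask((h, w), c, ax, liver_angle, wobble) & body
        liver_masks.append(m)
    liver = np.stack(liver_masks)

    # distractor organs: liver-like intensity, outside the liver
    distractors = np.zeros((h, w), dtype=bool)
    for _ in range(cfg.n_distractors):
        for _attempt in range(20):
            c = (rng.uniform(0.2, 0.8) * h, rng.uniform(0.2, 0.8) * w)
            ax = (h * rng.uniform(0.04, 0.10), w * rng.uniform(0.04, 0.10))
            d = _blob_mask((h, w), c, ax, rng.uniform(0, np.pi), {}) & body
            if d.any() and not (d & liver.any(axis=0)).any():
                distractors |= d
                break

    # intensities
    body_tex = _draw_range(rng, cfg.body_hu, (h, w), field_sigma=max(8, h // 16))
    liver_tex = _draw_range(rng, cfg.liver_hu, (h, w), field_sigma=max(8, h // 16))
    dist_tex = _draw_range(rng, cfg.distractor_hu, (h, w), field_sigma=max(8, h // 16))
    for z in range(n):
        sl = hu[z]
        sl[body] = body_tex[body]
        sl[distractors & ~liver[z]] = dist_tex[distractors & ~liver[z]]
        sl[liver[z]] = liver_tex[liver[z]]
    labels[liver] = 1

    # tumors: spheres (in index space) strictly inside the liver
    n_tumors = int(rng.integers(cfg.tumor_count_range[0], cfg.tumor_count_range[1] + 1))
    tumor_tex = _draw_range(rng, cfg.tumor_hu, (h, w), field_sigma=max(6, h // 24))
    for _ in range(n_tumors):
        radius = rng.uniform(*cfg.tumor_radius_range)
        placed = False
        for _attempt in range(50):
            zc = int(rng.integers(0, n))
            # in-plane clearance to the liver boundary on the central slice
            edt = ndimage.distance_transform_edt(liver[zc])
            ok = edt > radius + 2
            if not ok.any():
                continue
            idx = np.argwhere(ok)
            rc = idx[rng.integers(0, len(idx))]
            rz = max(1.0, radius / 3.0)  # flattened sphere along the stack
            fits = True
            spans = {}
            for z in range(max(0, int(zc - rz)), min(n, int(zc + rz) + 1)):
                frac = 1.0 - ((z - zc) / rz) ** 2
                if frac <= 0:
                    continue
                r_xy = radius * np.sqrt(frac)
                edt_z = ndimage.distance_transform_edt(liver[z])
                if edt_z[rc[0], rc[1]] <= r_xy + 1:
                    fits = False
                    break
                spans[z] = r_xy
            if not fits or not spans:
                continue
            yy, xx = np.mgrid[0:h, 0:w]
            for z, r_xy in spans.items():
                disk = (yy - rc[0]) ** 2 + (xx - rc[1]) ** 2 <= r_xy ** 2
                disk &= liver[z]
                labels[z][disk] = 2
                hu[z][disk] = tumor_tex[disk]
            placed = True
            break
        if not placed:
            raise PhantomError(
                f"could not place a tumor of radius {radius:.1f}px inside the liver "
                f"after bounded attempts (grid {cfg.grid}, seed {cfg.seed})"
            )

    if cfg.noise_sd > 0:
        hu += rng.normal(0.0, cfg.noise_sd, size=hu.shape)

    ct = CTVolume(hu.astype(np.float32), cfg.spacing, identifier=ident)
    gt = LabelVolume(labels, cfg.spacing, identifier=ident)
    return ct, gt


def generate_dataset(config: PhantomConfig, n_volumes: int):
    """Generate ``n_volumes`` independent phantoms plus summary statistics.

    Per-volume seeds are derived from ``config.seed`` so volumes are
    mutually independent and the whole dataset is reproducible.  Returns
    ``(pairs, stats)`` where stats reports liver area fraction and the
    fraction of slices containing tumor.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    import dataclasses

    pairs = []
    for i in range(n_volumes):
        sub = dataclasses.replace(config, seed=int((config.seed + 1) * 100003 + i) % (2**31))
        pairs.append(generate_volume(sub))

    liver_frac = []
    tumor_slices = 0
    total_slices = 0
    for _, gt in pairs:
        liver = gt.liver_mask
        liver_frac.append(liver.mean())
        tumor_slices += int((gt.tumor_mask.any(axis=(1, 2))).sum())
        total_slices += gt.labels.shape[0]
    stats = {
        "n_volumes": n_volumes,
        "n_slices": total_slices,
        "liver_area_fraction": float(np.mean(liver_frac)),
        "tumor_slice_fraction": tumor_slices / total_slices,
    }
    return pairs, stats
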