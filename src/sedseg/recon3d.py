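"""3-D reconstruction of stacked 2-D segmentation masks.

Adjacent per-slice masks are stacked into a binary voxel grid with
physical millimetre spacing; tumor/liver volume is estimated by voxel
counting, a triangulated iso-surface is extracted by marching cubes at
level 0.5, and translucent multi-view renderings (front / top / left /
bottom / right, with optional rotation about the slice axis) are
exported as PNG images.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from skimage import measure

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from mpl_toolkits.mplot3d.art3d import Poly3DCollection  # noqa: E402

__all__ = ["VoxelGrid", "Mesh3D", "stack_masks", "estimate_volume",
           "extract_surface", "render_views", "STANDARD_VIEWS"]

#: view name -> (elevation, azimuth) with z = slice axis pointing up
STANDARD_VIEWS = {
    "front": (0.0, -90.0),
    "top": (90.0, -90.0),
    "left": (0.0, 180.0),
    "bottom": (-90.0, -90.0),
    "right": (0.0, 0.0),
}


@dataclass
class VoxelGrid:
    """Binary (slice, row, col) grid with (slice_mm, row_mm, col_mm) spacing."""

    values: np.ndarray
    spacing: tuple

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("voxel grid must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")


@dataclass
class Mesh3D:
    """Triangulated surface in millimetre coordinates."""

    vertices: np.ndarray
    faces: np.ndarray
    volume_mm3: float
    source: str = "tumor"
    watertight: bool = False

    def export(self, path) -> None:
        """Write the mesh as PLY or STL, by file extension."""
        trimesh.Trimesh(self.vertices, self.faces, process=False).export(str(path))


def stack_masks(masks, pixel_spacing=(1.0, 1.0), slice_spacing: float = 1.0) -> VoxelGrid:
    """Stack ordered 2-D masks into a voxel grid with physical spacing."""
    masks = [np.asarray(m).astype(bool) for m in masks]
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].shape
    for i, m in enumerate(masks):
        if m.ndim != 2 or m.shape != shape:
            raise ValueError(f"mask {i} has shape {m.shape}, expected {shape}")
    if slice_spacing <= 0 or any(s <= 0 for s in pixel_spacing):
        raise ValueError("spacings must be positive")
    return VoxelGrid(np.stack(masks, axis=0),
                     (slice_spacing, pixel_spacing[0], pixel_spacing[1]))


def estimate_volume(grid: VoxelGrid) -> float:
    """Volume in mm^3: set-voxel count times the voxel volume (exact, linear)."""
    return float(grid.values.sum()) * grid.spacing[0] * grid.spacing[1] * grid.spacing[2]


def extract_surface(grid: VoxelGrid, source: str = "tumor") -> Mesh3D:
    """Marching-cubes iso-surface of the binary grid at level 0.5.

    The grid is zero-padded by one voxel so surfaces close at the array
    boundary; vertex coordinates are in millimetres with the padding
    offset removed.
    """
    if not grid.values.any():
        raise ValueError("cannot extract a surface from an empty grid")
    padded = np.pad(grid.values.astype(float), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=grid.spacing)
    verts = verts - np.asarray(grid.spacing)
    mesh = trimesh.Trimesh(verts, faces, process=False)
    return Mesh3D(vertices=verts, faces=faces, volume_mm3=float(abs(mesh.volume)),
                  source=source, watertight=bool(mesh.is_watertight))


def render_views(meshes, out_dir, views=tuple(STANDARD_VIEWS),
                 rotation_deg: float = 0.0, colors=None, opacities=None,
                 prefix: str = "view") -> dict:
    """Render translucent meshes from the requested viewpoints.

    ``rotation_deg`` rotates the camera about the slice (z) axis; 0 and
    360 degrees therefore produce identical images.  Returns a mapping
    view name -> written PNG path.
    """
    meshes = list(meshes)
    if not meshes:
        raise ValueError("need at least one mesh to render")
    unknown = [v for v in views if v not in STANDARD_VIEWS]
    if unknown:
        raise ValueError(f"unknown views {unknown}; choose from {list(STANDARD_VIEWS)}")
    if colors is None:
        palette = [(0.85, 0.3, 0.25), (0.25, 0.45, 0.8), (0.3, 0.7, 0.35)]
        colors = [palette[i % len(palette)] for i in range(len(meshes))]
    if opacities is None:
        opacities = [0.45] * len(meshes)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    all_pts = np.vstack([m.vertices for m in meshes])
    lo, hi = all_pts.min(axis=0), all_pts.max(axis=0)
    center = (lo + hi) / 2
    half = float((hi - lo).max()) / 2 + 1e-6

    written = {}
    for view in views:
        elev, azim = STANDARD_VIEWS[view]
        fig = plt.figure(figsize=(4, 4), dpi=110)
        ax = fig.add_subplot(111, projection="3d")
        for m, col, alpha in zip(meshes, colors, opacities):
            # mesh coords are (slice=z, row=y, col=x); plot as (x, y, z)
            tri = m.vertices[m.faces][:, :, ::-1]
            poly = Poly3DCollection(tri, alpha=alpha, facecolor=col,
                                    edgecolor="none")
            ax.add_collection3d(poly)
        ax.set_xlim(center[2] - half, center[2] + half)
        ax.set_ylim(center[1] - half, center[1] + half)
        ax.set_zlim(center[0] - half, center[0] + half)
        ax.view_init(elev=elev, azim=azim + rotation_deg % 360.0)
        ax.set_axis_off()
        path = out_dir / f"{prefix}_{view}.png"
        fig.savefig(path)
        plt.close(fig)
        written[view] = path
    return written
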