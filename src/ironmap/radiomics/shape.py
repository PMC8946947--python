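"""Shape descriptors: 16 3D features on the full ROI and 10 2D features on the
largest-area axial slice. Mesh-based quantities come from a marching-cubes
surface of the binary mask in physical (mm) coordinates."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull
from skimage import measure

#: Gaussian pre-smoothing (voxels) of the binary mask before surface
#: extraction; suppresses the staircase artifact that inflates the area of a
#: voxelized surface (a digitized ball then meshes to sphericity ~0.99
#: instead of ~0.92) at the cost of <2% mesh-volume shrinkage
_MESH_SMOOTHING = 0.7

from ..io_preproc import LabelMask

__all__ = ["shape_features", "SHAPE3D_NAMES", "SHAPE2D_NAMES"]

SHAPE3D_NAMES = (
    "Compactness1", "Compactness2", "Elongation", "Flatness", "LeastAxisLength",
    "MajorAxisLength", "Maximum2DDiameterColumn", "Maximum2DDiameterRow",
    "Maximum2DDiameterSlice", "Maximum3DDiameter", "MeshVolume",
    "MinorAxisLength", "Sphericity", "SurfaceArea", "SurfaceVolumeRatio",
    "VoxelVolume",
)

SHAPE2D_NAMES = (
    "Elongation", "MajorAxisLength", "MaximumDiameter", "MeshSurface",
    "MinorAxisLength", "Perimeter", "PerimeterSurfaceRatio", "PixelSurface",
    "SphericalDisproportion", "Sphericity",
)


def _axis_lengths(coords_mm: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the coordinate covariance (physical mm)."""
    centered = coords_mm - coords_mm.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    return np.clip(eig, 0.0, None)


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) == 1:
        return 0.0
    uniq = np.unique(points, axis=0)
    if len(uniq) > 3 and uniq.shape[1] <= 3:
        try:
            hull = ConvexHull(uniq, qhull_options="QJ")
            uniq = uniq[hull.vertices]
        except Exception:
            pass
    d2 = ((uniq[:, None, :] - uniq[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max()))


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


def _shape_3d(mask: np.ndarray, spacing: np.ndarray) -> dict[str, float]:
    n = int(mask.sum())
    voxel_volume = float(np.prod(spacing))
    coords = np.array(np.nonzero(mask)).T.astype(np.float64) * spacing

    f: dict[str, float] = {}
    f["VoxelVolume"] = n * voxel_volume

    padded = np.pad(mask.astype(np.float64), 2)
    if n > 1:
        smoothed = gaussian_filter(padded, _MESH_SMOOTHING)
        # tiny objects can smooth entirely below the iso level; mesh them raw
        if smoothed.max() > 0.5:
            padded = smoothed
        verts, faces, *_ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
        area = float(measure.mesh_surface_area(verts, faces))
        volume = _mesh_volume(verts, faces)
        surf_points = verts
    else:
        # a single voxel: closed-form cuboid surface
        a_, b_, c_ = spacing
        area = 2.0 * (a_ * b_ + b_ * c_ + a_ * c_)
        volume = voxel_volume
        surf_points = coords
    volume = max(volume, 1e-12)
    f["MeshVolume"] = volume
    f["SurfaceArea"] = area
    f["SurfaceVolumeRatio"] = area / volume
    f["Sphericity"] = (36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area
    f["Compactness1"] = volume / (np.sqrt(np.pi) * area**1.5)
    f["Compactness2"] = 36.0 * np.pi * volume**2 / area**3

    eig = _axis_lengths(coords)
    f["MajorAxisLength"] = 4.0 * np.sqrt(eig[0])
    f["MinorAxisLength"] = 4.0 * np.sqrt(eig[1])
    f["LeastAxisLength"] = 4.0 * np.sqrt(eig[2])
    f["Elongation"] = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    f["Flatness"] = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0

    f["Maximum3DDiameter"] = _max_pairwise(surf_points)
    # in-plane diameters: slice = axes (0,1), column = (0,2), row = (1,2)
    for name, keep in (
        ("Maximum2DDiameterSlice", (0, 1)),
        ("Maximum2DDiameterColumn", (0, 2)),
        ("Maximum2DDiameterRow", (1, 2)),
    ):
        drop = ({0, 1, 2} - set(keep)).pop()
        best = 0.0
        # group surface points by the dropped world axis, one plane at a time
        plane_key = np.round(surf_points[:, drop] / (spacing[drop] / 2.0)).astype(int)
        for key in np.unique(plane_key):
            pts = surf_points[plane_key == key][:, keep]
            if len(pts) > 1:
                best = max(best, _max_pairwise(pts))
        f[name] = best
    return f


def _shape_2d(sl: np.ndarray, spacing2: np.ndarray) -> dict[str, float]:
    n = int(sl.sum())
    pixel_area = float(np.prod(spacing2))
    coords = np.array(np.nonzero(sl)).T.astype(np.float64) * spacing2

    f: dict[str, float] = {}
    f["PixelSurface"] = n * pixel_area
    padded = np.pad(sl.astype(np.float64), 2)
    if n > 1:
        smoothed = gaussian_filter(padded, _MESH_SMOOTHING)
        if smoothed.max() > 0.5:
            padded = smoothed
    contours = measure.find_contours(padded, level=0.5)
    if contours:
        perimeter = 0.0
        area = 0.0
        for contour in contours:
            pts = (contour - 2.0) * spacing2
            perimeter += float(np.sqrt(((np.diff(pts, axis=0)) ** 2).sum(axis=1)).sum())
            x, y = pts[:, 0], pts[:, 1]
            area += 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    else:
        perimeter = 2.0 * (spacing2[0] + spacing2[1])
        area = pixel_area
    area = max(area, 1e-12)
    f["MeshSurface"] = area
    f["Perimeter"] = perimeter
    f["PerimeterSurfaceRatio"] = perimeter / area
    sph = 2.0 * np.sqrt(np.pi * area) / perimeter
    f["Sphericity"] = sph
    f["SphericalDisproportion"] = 1.0 / sph

    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    eig = np.clip(np.sort(np.linalg.eigvalsh(cov))[::-1], 0.0, None)
    f["MajorAxisLength"] = 4.0 * np.sqrt(eig[0])
    f["MinorAxisLength"] = 4.0 * np.sqrt(eig[1])
    f["Elongation"] = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    f["MaximumDiameter"] = _max_pairwise(coords)
    return f


def shape_features(mask: LabelMask, structure: str) -> tuple[dict, dict]:
    """Return (shape3d, shape2d) feature dicts for one structure.

    The 2D set is computed on the axial (third-axis) slice with the largest
    in-plane pixel count.
    """
    roi = mask.structure_mask(structure)
    if not roi.any():
        raise ValueError(f"structure {structure!r} has no voxels")
    spacing = mask.grid.spacing
    f3 = _shape_3d(roi, spacing)

    slice_counts = roi.sum(axis=(0, 1))
    k = int(np.argmax(slice_counts))
    f2 = _shape_2d(roi[:, :, k], spacing[:2])
    return ({k: f3[k] for k in SHAPE3D_NAMES}, {k: f2[k] for k in SHAPE2D_NAMES})
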