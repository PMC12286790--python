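"""Geometric shape descriptors of a 3D binary region (14 features).

Surface area comes from a marching-cubes mesh of the padded mask; axis
lengths from a PCA of physical voxel-centre coordinates; the maximum 3D
diameter is the largest pairwise voxel-centre distance (computed on the
convex hull for speed).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

__all__ = ["SHAPE_NAMES", "shape_features"]

SHAPE_NAMES = (
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Compactness1",
    "Compactness2",
    "SphericalDisproportion",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)


def _max_pairwise(points: np.ndarray) -> float:
    if points.shape[0] < 2:
        return 0.0
    if points.shape[0] > 10:
        try:
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except QhullError:
            pass  # degenerate (coplanar etc.) -> brute force on all points
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max()))


def shape_features(mask_region: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> dict[str, float]:
    mask = np.asarray(mask_region, dtype=bool)
    if not mask.any():
        raise ValueError("empty region")
    spacing = np.asarray(spacing, dtype=float)
    voxel_vol = float(np.prod(spacing))
    n = int(mask.sum())
    volume = n * voxel_vol

    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    area = float(measure.mesh_surface_area(verts, faces))

    coords = np.argwhere(mask) * spacing[None, :]
    max3d = _max_pairwise(coords)

    max2d = 0.0
    for z in np.unique(np.argwhere(mask)[:, 2]):
        pts = np.argwhere(mask[:, :, z]) * spacing[None, :2]
        max2d = max(max2d, _max_pairwise(pts))

    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / n  # population covariance
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    axes = 4.0 * np.sqrt(eig)
    if eig[0] > 0:
        elong = float(np.sqrt(eig[1] / eig[0]))
        flat = float(np.sqrt(eig[2] / eig[0]))
    else:  # single voxel / degenerate: treated as a point sphere
        elong = flat = 1.0

    sphericity = (36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area
    return {
        "VoxelVolume": volume,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / volume,
        "Sphericity": sphericity,
        "Compactness1": volume / (np.sqrt(np.pi) * area**1.5),
        "Compactness2": 36.0 * np.pi * volume**2 / area**3,
        "SphericalDisproportion": 1.0 / sphericity,
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": max2d,
        "MajorAxisLength": float(axes[0]),
        "MinorAxisLength": float(axes[1]),
        "LeastAxisLength": float(axes[2]),
        "Elongation": elong,
        "Flatness": flat,
    }
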