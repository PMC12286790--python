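"""APTw quantification: MTR asymmetry at +/-3.5 ppm from z-spectrum stacks,
and the conventional three-ROI mean measurement protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ZSpectrumStack",
    "APTwMap",
    "ROIMeasurement",
    "compute_aptw_map",
    "measure_three_roi_mean",
]

#: nearest-ppm matching tolerance when locating the +/-3.5 ppm offsets
OFFSET_TOL_PPM = 0.05


@dataclass
class ZSpectrumStack:
    """Saturated signals over frequency offsets plus the unsaturated signal.

    ``signals`` has shape ``(n_offsets, *grid)``; ``s0`` has shape ``grid``.
    """

    signals: np.ndarray
    offsets: np.ndarray
    s0: np.ndarray

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        if self.signals.shape[0] != self.offsets.size:
            raise ValueError("signals first axis must match number of offsets")
        if self.signals.shape[1:] != self.s0.shape:
            raise ValueError("signals grid must match s0 grid")

    def offset_index(self, ppm: float) -> int:
        d = np.abs(self.offsets - ppm)
        i = int(np.argmin(d))
        if d[i] > OFFSET_TOL_PPM:
            raise ValueError(
                f"no offset within {OFFSET_TOL_PPM} ppm of {ppm:+.2f}; "
                f"available: {np.sort(self.offsets).tolist()}"
            )
        return i


@dataclass
class APTwMap:
    """Per-voxel APTw values in percent units, valid on ``mask`` only."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not np.isfinite(self.values[self.mask]).all():
            raise ValueError("APTw values must be finite on the mask")


@dataclass
class ROIMeasurement:
    roi_centers: list[tuple[int, int, int]]
    roi_radius_mm: float
    per_roi_means: np.ndarray
    summary_mean: float = field(init=False)

    def __post_init__(self):
        self.per_roi_means = np.asarray(self.per_roi_means, dtype=float)
        if self.per_roi_means.size != 3:
            raise ValueError("exactly three ROI means expected")
        self.summary_mean = float(self.per_roi_means.mean())


def compute_aptw_map(z: ZSpectrumStack, mask) -> APTwMap:
    """APTw% = (S(-3.5) - S(+3.5)) / S0 * 100, voxelwise on the mask.

    Voxels with s0 <= 0 are flagged invalid and removed from the output mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != z.s0.shape:
        raise ValueError("mask shape must match z-spectrum grid")
    i_neg = z.offset_index(-3.5)
    i_pos = z.offset_index(+3.5)

    valid = mask & (z.s0 > 0)
    n_bad = int(mask.sum() - valid.sum())
    if n_bad:
        warnings.warn(f"{n_bad} voxels with s0 <= 0 excluded from mask", stacklevel=2)

    values = np.zeros(z.s0.shape, dtype=float)
    num = z.signals[i_neg] - z.signals[i_pos]
    values[valid] = num[valid] / z.s0[valid] * 100.0
    return APTwMap(values=values, mask=valid)


# ---------------------------------------------------------------------------
# Three-ROI protocol
# ---------------------------------------------------------------------------


def _largest_diameter_slice(mask: np.ndarray, axis: int = 2) -> int:
    """Axial slice index maximizing in-mask pixel count; ties -> lowest index."""
    sum_axes = tuple(a for a in range(mask.ndim) if a != axis)
    counts = mask.sum(axis=sum_axes)
    return int(np.argmax(counts))  # argmax returns first (lowest) maximizer


def _feasible_centers(region2d: np.ndarray, radius_vox: float) -> np.ndarray:
    """Boolean map of pixels whose disc of given radius fits in the region."""
    dist = ndimage.distance_transform_edt(region2d)
    return dist >= radius_vox


def measure_three_roi_mean(
    aptw_map: APTwMap,
    mask=None,
    exclusion_mask=None,
    roi_radius_mm: float = 3.0,
    spacing=(1.0, 1.0, 1.0),
    seed: int | None = None,
) -> ROIMeasurement:
    """Place three disjoint circular ROIs on the largest-diameter slice and
    average the map within each.

    Placement is a deterministic greedy farthest-point rule over the feasible
    region (pixels whose disc fits inside mask minus exclusion); ``seed`` is
    accepted for interface symmetry but placement itself is deterministic.
    """
    del seed
    mask = aptw_map.mask if mask is None else np.asarray(mask, dtype=bool)
    region = mask.copy()
    if exclusion_mask is not None:
        region &= ~np.asarray(exclusion_mask, dtype=bool)
    if not region.any():
        raise ValueError("empty ROI-eligible region")

    spacing = np.asarray(spacing, dtype=float)
    if spacing[0] != spacing[1]:
        raise ValueError("in-plane spacing must be isotropic for circular ROIs")
    radius_vox = roi_radius_mm / spacing[0]

    z = _largest_diameter_slice(region)
    sl = region[:, :, z]
    feasible = _feasible_centers(sl, radius_vox)
    if not feasible.any():
        dist = ndimage.distance_transform_edt(sl)
        raise ValueError(
            f"cannot fit a circle of radius {roi_radius_mm} mm on slice {z}; "
            f"achievable maximum radius is {dist.max() * spacing[0]:.2f} mm"
        )

    coords = np.argwhere(feasible).astype(float)
    dist_map = ndimage.distance_transform_edt(sl)
    # first centre: deepest feasible point (ties -> lexicographic order)
    depth = dist_map[feasible.nonzero()]
    first = np.flatnonzero(depth == depth.max())[0]
    centers = [coords[first]]
    min_sep = 2.0 * radius_vox  # disjoint circles
    for _ in range(2):
        d = np.min(
            np.linalg.norm(coords[:, None, :] - np.asarray(centers)[None, :, :], axis=2),
            axis=1,
        )
        ok = d >= min_sep
        if not ok.any():
            raise ValueError(
                "cannot fit three disjoint circular ROIs of radius "
                f"{roi_radius_mm} mm on slice {z}; reduce roi_radius_mm "
                f"(feasible single-circle max: {dist_map.max() * spacing[0]:.2f} mm)"
            )
        cand = np.flatnonzero(ok)
        centers.append(coords[cand[np.argmax(d[cand])]])

    ii, jj = np.mgrid[0 : sl.shape[0], 0 : sl.shape[1]]
    means = []
    int_centers = []
    for c in centers:
        disc = ((ii - c[0]) ** 2 + (jj - c[1]) ** 2) <= radius_vox**2
        disc &= sl
        means.append(float(aptw_map.values[:, :, z][disc].mean()))
        int_centers.append((int(round(c[0])), int(round(c[1])), z))
    return ROIMeasurement(
        roi_centers=int_centers, roi_radius_mm=roi_radius_mm, per_roi_means=np.array(means)
    )
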