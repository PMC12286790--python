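"""Tumor habitat partitioning: voxel-level local radiomic features over a
3x3x3 sliding window, per-tumor K-means clustering, and cluster-count
selection with the Calinski-Harabasz index.

The 13 voxel-level descriptors (fixed set): window mean, variance, skewness,
kurtosis, min, max, range, energy, 8-bin Shannon entropy, and four GLCM
descriptors (contrast, homogeneity, correlation, energy) at 8 gray levels.
Habitats are relabeled in ascending order of mean APTw, so habitat k is
always the highest-signal subregion ("h3" when k = 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

__all__ = [
    "VoxelFeatureMap",
    "HabitatMap",
    "VOXEL_FEATURE_NAMES",
    "extract_voxel_features",
    "kmeans_partition",
    "calinski_harabasz",
    "select_habitats",
]

VOXEL_FEATURE_NAMES = (
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "min",
    "max",
    "range",
    "energy",
    "entropy",
    "glcm_contrast",
    "glcm_homogeneity",
    "glcm_correlation",
    "glcm_energy",
)

_N_GRAY = 8
_MIN_WINDOW_VOXELS = 9  # centre voxel + at least 8 in-mask neighbours


@dataclass
class VoxelFeatureMap:
    features: np.ndarray  # (n_voxels, 13)
    feature_names: tuple[str, ...]
    coords: np.ndarray  # (n_voxels, 3) voxel indices
    shape: tuple[int, int, int]

    def __post_init__(self):
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError("feature count mismatch")


@dataclass
class HabitatMap:
    labels: np.ndarray  # integer volume, 0 = background
    k: int
    ch_scores: dict[int, float]
    ordering_key: np.ndarray  # per-habitat mean APTw, ascending

    def __post_init__(self):
        found = np.unique(self.labels)
        if not np.isin(found, np.arange(self.k + 1)).all():
            raise ValueError("labels must lie in {0..k}")
        if np.any(np.diff(self.ordering_key) < -1e-9):
            raise ValueError("habitats must be ordered by ascending mean APTw")


# ---------------------------------------------------------------------------
# voxel features
# ---------------------------------------------------------------------------

_OFFSETS = np.array([(i, j, l) for i in (-1, 0, 1) for j in (-1, 0, 1) for l in (-1, 0, 1)])

# 13 unique GLCM directions (half of the 26-neighbourhood)
_DIRECTIONS = np.array(
    [d for d in _OFFSETS.tolist() if d != [0, 0, 0] and (d > [0, 0, 0])], dtype=int
)

# pairs of window positions (indices into the 27-vector) adjacent along each
# direction, pooled over all 13 directions
_pos = {tuple(o): i for i, o in enumerate(_OFFSETS)}
_PAIR_A, _PAIR_B = [], []
for _d in _DIRECTIONS:
    for _o in _OFFSETS:
        _t = tuple(_o + _d)
        if _t in _pos:
            _PAIR_A.append(_pos[tuple(_o)])
            _PAIR_B.append(_pos[_t])
_PAIR_A = np.array(_PAIR_A)
_PAIR_B = np.array(_PAIR_B)


def _window_views(vol: np.ndarray, mask: np.ndarray):
    """Per-centre (n, 27) window values and validity for eligible centres."""
    inner = np.zeros_like(mask)
    inner[1:-1, 1:-1, 1:-1] = True
    centers = np.argwhere(mask & inner)
    if centers.size == 0:
        raise ValueError("mask has no interior voxels eligible for a 3x3x3 window")
    idx = centers[:, None, :] + _OFFSETS[None, :, :]  # (n, 27, 3)
    flat = np.ravel_multi_index(idx.reshape(-1, 3).T, vol.shape)
    vals = vol.ravel()[flat].reshape(-1, 27)
    valid = mask.ravel()[flat].reshape(-1, 27)
    keep = valid.sum(axis=1) >= _MIN_WINDOW_VOXELS
    if not keep.any():
        raise ValueError(
            "no voxel has the required >= 9 in-mask window neighbours"
        )
    return centers[keep], vals[keep], valid[keep]


def extract_voxel_features(vol: np.ndarray, mask: np.ndarray) -> VoxelFeatureMap:
    """13 local descriptors per in-mask voxel whose 3x3x3 window fits in the
    volume and contains >= 9 in-mask voxels (mask-restricted statistics)."""
    vol = np.asarray(vol, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if vol.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")

    centers, vals, valid = _window_views(vol, mask)
    n = centers.shape[0]
    cnt = valid.sum(axis=1).astype(float)
    v = np.where(valid, vals, 0.0)

    mean = v.sum(axis=1) / cnt
    dev = np.where(valid, vals - mean[:, None], 0.0)
    m2 = (dev**2).sum(axis=1) / cnt
    m3 = (dev**3).sum(axis=1) / cnt
    m4 = (dev**4).sum(axis=1) / cnt
    sd = np.sqrt(m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(sd > 0, m3 / sd**3, 0.0)
        kurt = np.where(m2 > 0, m4 / m2**2, 0.0)
    vmin = np.where(valid, vals, np.inf).min(axis=1)
    vmax = np.where(valid, vals, -np.inf).max(axis=1)
    vrange = vmax - vmin
    energy = (v**2).sum(axis=1) / cnt

    # discretise each window to 8 levels between its own min and max
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(vrange > 0, (_N_GRAY - 1e-9) / vrange, 0.0)
    levels = np.clip(((vals - vmin[:, None]) * scale[:, None]).astype(int), 0, _N_GRAY - 1)

    # 8-bin Shannon entropy of the window histogram
    hist = np.zeros((n, _N_GRAY))
    row = np.repeat(np.arange(n), 27)
    np.add.at(hist, (row, levels.ravel()), valid.ravel().astype(float))
    p = hist / cnt[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)

    # GLCM over 13 directions, pairs restricted to in-mask voxels
    g1 = levels[:, _PAIR_A]
    g2 = levels[:, _PAIR_B]
    pair_ok = valid[:, _PAIR_A] & valid[:, _PAIR_B]
    glcm = np.zeros((n, _N_GRAY, _N_GRAY))
    row = np.repeat(np.arange(n), _PAIR_A.size)
    np.add.at(glcm, (row, g1.ravel(), g2.ravel()), pair_ok.ravel().astype(float))
    glcm = glcm + glcm.transpose(0, 2, 1)
    tot = glcm.sum(axis=(1, 2))
    tot[tot == 0] = 1.0
    P = glcm / tot[:, None, None]

    i_idx = np.arange(_N_GRAY)
    ii, jj = np.meshgrid(i_idx, i_idx, indexing="ij")
    contrast = (P * (ii - jj)[None] ** 2).sum(axis=(1, 2))
    homogeneity = (P / (1.0 + np.abs(ii - jj))[None]).sum(axis=(1, 2))
    genergy = (P**2).sum(axis=(1, 2))
    mu_i = (P * ii[None]).sum(axis=(1, 2))
    mu_j = (P * jj[None]).sum(axis=(1, 2))
    var_i = (P * (ii[None] - mu_i[:, None, None]) ** 2).sum(axis=(1, 2))
    var_j = (P * (jj[None] - mu_j[:, None, None]) ** 2).sum(axis=(1, 2))
    cov = (P * (ii[None] - mu_i[:, None, None]) * (jj[None] - mu_j[:, None, None])).sum(
        axis=(1, 2)
    )
    denom = np.sqrt(var_i * var_j)
    correlation = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 1.0)

    feats = np.column_stack(
        [mean, m2, skew, kurt, vmin, vmax, vrange, energy, entropy,
         contrast, homogeneity, correlation, genergy]
    )
    return VoxelFeatureMap(
        features=feats,
        feature_names=VOXEL_FEATURE_NAMES,
        coords=centers,
        shape=vol.shape,
    )


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _zscore(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def kmeans_partition(
    fmap: VoxelFeatureMap,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """K-means (k-means++ init, Lloyd iterations) on within-tumor z-scored
    features; returns (labels in 0..k-1 per feature row, inertia)."""
    n = fmap.features.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds voxel count {n}")
    X = _zscore(fmap.features)
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_init, max_iter=max_iter,
        tol=tol, random_state=seed, algorithm="lloyd",
    ).fit(X)
    return km.labels_, float(km.inertia_)


def calinski_harabasz(features: np.ndarray, labeling: np.ndarray) -> float:
    """CH = [trace(B)/(k-1)] / [trace(W)/(n-k)] with between/within scatter."""
    X = np.asarray(features, dtype=float)
    lab = np.asarray(labeling)
    groups = np.unique(lab)
    k = groups.size
    n = X.shape[0]
    if k < 2:
        raise ValueError("need at least 2 clusters")
    grand = X.mean(axis=0)
    tr_b = 0.0
    tr_w = 0.0
    for g in groups:
        Xi = X[lab == g]
        if Xi.shape[0] == 0:
            raise ValueError("empty cluster")
        ci = Xi.mean(axis=0)
        tr_b += Xi.shape[0] * float(((ci - grand) ** 2).sum())
        tr_w += float(((Xi - ci) ** 2).sum())
    if tr_w == 0:
        return np.inf
    return (tr_b / (k - 1)) / (tr_w / (n - k))


def _fill_to_mask(label_vol: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Assign unlabeled in-mask voxels the label of the nearest labeled voxel
    so that habitats partition the full mask."""
    missing = mask & (label_vol == 0)
    if not missing.any():
        return label_vol
    _, idx = ndimage.distance_transform_edt(label_vol == 0, return_indices=True)
    filled = label_vol.copy()
    filled[missing] = label_vol[tuple(i[missing] for i in idx)]
    return filled


def select_habitats(
    fmap: VoxelFeatureMap,
    vol_aptw: np.ndarray,
    mask: np.ndarray,
    k_range: tuple[int, int] = (3, 10),
    seed: int = 0,
    n_init: int = 10,
) -> HabitatMap:
    """Cluster at every K in ``k_range``, select the K with the highest
    Calinski-Harabasz index (ties toward smaller K) and relabel habitats in
    ascending order of mean APTw."""
    n = fmap.features.shape[0]
    if n < 10:
        raise ValueError("need at least 10 feature voxels to select habitats")
    lo, hi = k_range
    if n < hi:
        warnings.warn(f"only {n} voxels: shrinking k range from {hi} to {n}", stacklevel=2)
        hi = n
    if hi < lo:
        raise ValueError("voxel count below the minimum cluster count")

    X = _zscore(fmap.features)
    ch_scores: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in range(lo, hi + 1):
        lab, _ = kmeans_partition(fmap, k, seed=seed, n_init=n_init)
        if np.unique(lab).size < k:  # degenerate solution
            ch_scores[k] = -np.inf
            continue
        ch_scores[k] = calinski_harabasz(X, lab)
        labelings[k] = lab
    best_k = max(sorted(ch_scores), key=lambda k: (ch_scores[k], -k))
    lab = labelings[best_k]

    # order clusters by mean APTw at their voxel coordinates
    aptw_at = vol_aptw[tuple(fmap.coords.T)]
    means = np.array([aptw_at[lab == c].mean() for c in range(best_k)])
    order = np.argsort(means, kind="stable")
    relabel = np.empty(best_k, dtype=int)
    relabel[order] = np.arange(1, best_k + 1)
    new_lab = relabel[lab]

    label_vol = np.zeros(fmap.shape, dtype=np.uint8)
    label_vol[tuple(fmap.coords.T)] = new_lab
    label_vol = _fill_to_mask(label_vol, np.asarray(mask, dtype=bool))
    return HabitatMap(
        labels=label_vol, k=best_k, ch_scores=ch_scores, ordering_key=np.sort(means)
    )
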