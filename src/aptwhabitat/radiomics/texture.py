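"""Gray-level texture matrices and their descriptors (75 features):

* GLCM, 24 features, 13-direction averaging, symmetric matrices;
* GLRLM, 16 features, 13-direction averaging;
* GLSZM, 16 features, 26-connected zones;
* GLDM, 14 features, alpha = 0, dependence j = dependent neighbours + 1;
* NGTDM, 5 features, 26-neighbourhood mean differences.

Input is a 3D integer array over the region bounding box with 0 marking
voxels outside the region and 1..Ng the discretized gray levels inside.
Degenerate regions (a single gray level) produce the limit values of each
feature and emit a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

__all__ = ["TEXTURE_NAMES", "discretize", "texture_features"]

_EPS = np.finfo(float).eps

_DIRECTIONS = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

_OFF26 = [
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]

GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
    "Imc1", "Imc2", "InverseVariance", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)
GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)
NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

TEXTURE_NAMES = (
    tuple(f"glcm_{n}" for n in GLCM_NAMES)
    + tuple(f"glrlm_{n}" for n in GLRLM_NAMES)
    + tuple(f"glszm_{n}" for n in GLSZM_NAMES)
    + tuple(f"gldm_{n}" for n in GLDM_NAMES)
    + tuple(f"ngtdm_{n}" for n in NGTDM_NAMES)
)
assert len(TEXTURE_NAMES) == 75


def discretize(values: np.ndarray, gray_levels: int) -> np.ndarray:
    """Equal-width min-max discretization into 1..gray_levels."""
    x = np.asarray(values, dtype=float)
    rng = np.ptp(x)
    if rng == 0:
        return np.ones(x.shape, dtype=int)
    lev = np.floor((x - x.min()) / rng * gray_levels).astype(int) + 1
    return np.clip(lev, 1, gray_levels)


def gray_volume(values: np.ndarray, coords: np.ndarray, gray_levels: int) -> np.ndarray:
    """Bounding-box gray-level array (0 outside the region) from region voxel
    values and their integer coordinates."""
    lev = discretize(values, gray_levels)
    lo = coords.min(axis=0)
    shape = coords.max(axis=0) - lo + 1
    out = np.zeros(tuple(shape), dtype=int)
    out[tuple((coords - lo).T)] = lev
    return out


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def _pair_slices(d, shape):
    src, dst = [], []
    for o, s in zip(d, shape):
        if o >= 0:
            src.append(slice(0, s - o))
            dst.append(slice(o, s))
        else:
            src.append(slice(-o, s))
            dst.append(slice(0, s + o))
    return tuple(src), tuple(dst)


def _glcm_matrix(gray: np.ndarray, d, ng: int) -> np.ndarray | None:
    src, dst = _pair_slices(d, gray.shape)
    g1 = gray[src].ravel()
    g2 = gray[dst].ravel()
    ok = (g1 > 0) & (g2 > 0)
    if not ok.any():
        return None
    m = np.zeros((ng, ng))
    np.add.at(m, (g1[ok] - 1, g2[ok] - 1), 1.0)
    return m + m.T


def _glcm_features(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sig_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sig_y = np.sqrt(((i - mu_y) ** 2 * py).sum())

    k_diff = np.arange(ng, dtype=float)  # |i-j| in 0..ng-1
    p_diff = np.array([P[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.array([P[(ii + jj) == k].sum() for k in k_sum])

    da = (k_diff * p_diff).sum()
    hx = -(px[px > 0] * np.log2(px[px > 0])).sum()
    hy = -(py[py > 0] * np.log2(py[py > 0])).sum()
    hxy = -(P[P > 0] * np.log2(P[P > 0])).sum()
    pxpy = np.outer(px, py)
    nz = (P > 0) & (pxpy > 0)
    hxy1 = -(P[nz] * np.log2(pxpy[nz])).sum()
    nz2 = pxpy > 0
    hxy2 = -(pxpy[nz2] * np.log2(pxpy[nz2])).sum()

    if max(hx, hy) > 0:
        imc1 = (hxy - hxy1) / max(hx, hy)
    else:
        imc1 = 0.0
    imc2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))) if hxy2 >= hxy else 0.0

    if sig_x > 0 and sig_y > 0:
        corr = ((P * ii * jj).sum() - mu_x * mu_y) / (sig_x * sig_y)
    else:
        corr = 1.0

    # MCC: second largest eigenvalue of Q
    keep = (px > 0) & (py > 0)
    if keep.sum() > 1:
        Pk = P[np.ix_(keep, keep)]
        pxk = px[keep]
        pyk = py[keep]
        Q = (Pk / pxk[:, None]) @ (Pk / pyk[:, None]).T
        eig = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, eig[-2])))
    else:
        mcc = 1.0

    diff_sq = np.abs(ii - jj)
    off_diag = diff_sq > 0
    inv_var = (P[off_diag] / diff_sq[off_diag] ** 2).sum() if off_diag.any() else 0.0

    return {
        "Autocorrelation": float((P * ii * jj).sum()),
        "JointAverage": float(mu_x),
        "ClusterProminence": float((P * (ii + jj - mu_x - mu_y) ** 4).sum()),
        "ClusterShade": float((P * (ii + jj - mu_x - mu_y) ** 3).sum()),
        "ClusterTendency": float((P * (ii + jj - mu_x - mu_y) ** 2).sum()),
        "Contrast": float((P * (ii - jj) ** 2).sum()),
        "Correlation": float(corr),
        "DifferenceAverage": float(da),
        "DifferenceEntropy": float(-(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])).sum()),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((P / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "Idn": float((P / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": float(imc2),
        "InverseVariance": float(inv_var),
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": float(hxy),
        "MCC": mcc,
        "MaximumProbability": float(P.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum()),
        "SumSquares": float((P * (ii - mu_x) ** 2).sum()),
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


def _glrlm_matrix(gray: np.ndarray, d, ng: int) -> np.ndarray:
    """Run-length matrix along one direction via sort-by-line decomposition."""
    coords = np.argwhere(gray > 0)
    g = gray[tuple(coords.T)]
    max_run = max(gray.shape)
    R = np.zeros((ng, max_run))
    if coords.shape[0] == 0:
        return R
    d = np.asarray(d)
    axis = int(np.flatnonzero(d)[0])
    t = coords[:, axis] * np.sign(d[axis])
    line = coords - t[:, None] * d[None, :]
    order = np.lexsort((t, line[:, 2], line[:, 1], line[:, 0]))
    t, g, line = t[order], g[order], line[order]
    new_line = np.r_[True, (np.diff(line, axis=0) != 0).any(axis=1)]
    new_run = new_line | np.r_[True, np.diff(t) != 1] | np.r_[True, np.diff(g) != 0]
    starts = np.flatnonzero(new_run)
    lengths = np.diff(np.r_[starts, t.size])
    np.add.at(R, (g[starts] - 1, lengths - 1), 1.0)
    return R


def _rlm_style_features(M: np.ndarray, n_voxels: int, names) -> dict:
    """Shared feature algebra for run-length (size = run length) and size-zone
    (size = zone area) matrices."""
    nr = M.sum()
    if nr == 0:
        return {n: 0.0 for n in names}
    g = np.arange(1, M.shape[0] + 1, dtype=float)
    r = np.arange(1, M.shape[1] + 1, dtype=float)
    gg, rr = np.meshgrid(g, r, indexing="ij")
    p = M / nr
    mu_g = (p * gg).sum()
    mu_r = (p * rr).sum()
    pg = M.sum(axis=1)
    pr = M.sum(axis=0)
    short = (M / rr**2).sum() / nr
    long_ = (M * rr**2).sum() / nr
    out = {
        names[0]: float(short),
        names[1]: float(long_),
        names[2]: float((pg**2).sum() / nr),
        names[3]: float((pg**2).sum() / nr**2),
        names[4]: float((pr**2).sum() / nr),
        names[5]: float((pr**2).sum() / nr**2),
        names[6]: float(nr / n_voxels),
        names[7]: float((p * (gg - mu_g) ** 2).sum()),
        names[8]: float((p * (rr - mu_r) ** 2).sum()),
        names[9]: float(-(p[p > 0] * np.log2(p[p > 0])).sum()),
        names[10]: float((M / gg**2).sum() / nr),
        names[11]: float((M * gg**2).sum() / nr),
        names[12]: float((M / (gg**2 * rr**2)).sum() / nr),
        names[13]: float((M * gg**2 / rr**2).sum() / nr),
        names[14]: float((M * rr**2 / gg**2).sum() / nr),
        names[15]: float((M * rr**2 * gg**2).sum() / nr),
    }
    return out


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------


def _glszm_matrix(gray: np.ndarray, ng: int, n_voxels: int) -> np.ndarray:
    structure = np.ones((3, 3, 3), dtype=int)
    S = np.zeros((ng, n_voxels))
    for g in np.unique(gray[gray > 0]):
        lab, nlab = ndimage.label(gray == g, structure=structure)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        np.add.at(S, (g - 1, sizes - 1), 1.0)
    return S


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------


def _gldm_matrix(gray: np.ndarray, ng: int, alpha: float = 0.0) -> np.ndarray:
    inside = gray > 0
    dep = np.zeros(gray.shape, dtype=int)
    for d in _OFF26:
        src, dst = _pair_slices(d, gray.shape)
        ok = inside[src] & inside[dst] & (np.abs(gray[src] - gray[dst]) <= alpha)
        dep[src] += ok
    # dependence index j = dependent neighbours + 1
    D = np.zeros((ng, 27))
    np.add.at(D, (gray[inside] - 1, dep[inside]), 1.0)
    return D


def _gldm_features(D: np.ndarray) -> dict[str, float]:
    nz = D.sum()
    g = np.arange(1, D.shape[0] + 1, dtype=float)
    j = np.arange(1, D.shape[1] + 1, dtype=float)
    gg, jj = np.meshgrid(g, j, indexing="ij")
    p = D / nz
    mu_g = (p * gg).sum()
    mu_j = (p * jj).sum()
    pg = D.sum(axis=1)
    pj = D.sum(axis=0)
    return {
        "SmallDependenceEmphasis": float((D / jj**2).sum() / nz),
        "LargeDependenceEmphasis": float((D * jj**2).sum() / nz),
        "GrayLevelNonUniformity": float((pg**2).sum() / nz),
        "DependenceNonUniformity": float((pj**2).sum() / nz),
        "DependenceNonUniformityNormalized": float((pj**2).sum() / nz**2),
        "GrayLevelVariance": float((p * (gg - mu_g) ** 2).sum()),
        "DependenceVariance": float((p * (jj - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(p[p > 0] * np.log2(p[p > 0])).sum()),
        "LowGrayLevelEmphasis": float((D / gg**2).sum() / nz),
        "HighGrayLevelEmphasis": float((D * gg**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((D / (gg**2 * jj**2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((D * gg**2 / jj**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((D * jj**2 / gg**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((D * jj**2 * gg**2).sum() / nz),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------


def _ngtdm_features(gray: np.ndarray, ng: int) -> dict[str, float]:
    inside = gray > 0
    nbr_sum = np.zeros(gray.shape)
    nbr_cnt = np.zeros(gray.shape)
    for d in _OFF26:
        src, dst = _pair_slices(d, gray.shape)
        ok = inside[dst]
        nbr_sum[src] += np.where(ok, gray[dst], 0)
        nbr_cnt[src] += ok
    has_nbr = inside & (nbr_cnt > 0)
    diffs = np.zeros(gray.shape)
    diffs[has_nbr] = np.abs(gray[has_nbr] - nbr_sum[has_nbr] / nbr_cnt[has_nbr])

    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    np.add.at(n_i, gray[has_nbr] - 1, 1.0)
    np.add.at(s_i, gray[has_nbr] - 1, diffs[has_nbr])
    n = n_i.sum()
    if n == 0:  # isolated voxels only: no gray-tone differences at all
        return {k: 0.0 for k in ("Contrast", "Busyness", "Complexity", "Strength")} | {
            "Coarseness": 1e6
        }
    p_i = n_i / n
    i = np.arange(1, ng + 1, dtype=float)
    present = p_i > 0
    ngp = int(present.sum())

    coarse_den = (p_i * s_i).sum()
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp > 1:
        ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
        pi, pj = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        contrast = (pi * pj * (ii - jj) ** 2).sum() / (ngp * (ngp - 1)) * s_i.sum() / n
        busy_den = np.abs(i[present][:, None] * p_i[present][:, None]
                          - i[present][None, :] * p_i[present][None, :]).sum()
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        si_, sj_ = np.meshgrid(s_i[present], s_i[present], indexing="ij")
        complexity = (np.abs(ii - jj) * (pi * si_ + pj * sj_) / (pi + pj)).sum() / n
        strength_num = ((pi + pj) * (ii - jj) ** 2).sum()
        strength = strength_num / s_i.sum() if s_i.sum() > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------


def texture_features(
    values: np.ndarray,
    coords: np.ndarray,
    gray_levels: int = 16,
) -> dict[str, float]:
    """All 75 texture descriptors for a region given its voxel values and
    integer voxel coordinates."""
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=int)
    if values.size == 0:
        raise ValueError("texture requires at least 1 voxel")
    if np.ptp(values) == 0:
        warnings.warn(
            "single gray level present: texture matrices are degenerate, "
            "features take their limit values",
            stacklevel=2,
        )
    gray = gray_volume(values, coords, gray_levels)
    ng = gray_levels
    n_vox = int(values.size)
    out: dict[str, float] = {}

    # GLCM: average features over directions with at least one pair
    acc: list[dict[str, float]] = []
    for d in _DIRECTIONS:
        m = _glcm_matrix(gray, d, ng)
        if m is None:
            continue
        acc.append(_glcm_features(m / m.sum()))
    for name in GLCM_NAMES:
        out[f"glcm_{name}"] = (
            float(np.mean([a[name] for a in acc])) if acc else 0.0
        )

    acc = []
    for d in _DIRECTIONS:
        R = _glrlm_matrix(gray, d, ng)
        acc.append(_rlm_style_features(R, n_vox, GLRLM_NAMES))
    for name in GLRLM_NAMES:
        out[f"glrlm_{name}"] = float(np.mean([a[name] for a in acc]))

    S = _glszm_matrix(gray, ng, n_vox)
    sz = _rlm_style_features(S, n_vox, GLSZM_NAMES)
    for name in GLSZM_NAMES:
        out[f"glszm_{name}"] = sz[name]

    D = _gldm_matrix(gray, ng)
    gd = _gldm_features(D)
    for name in GLDM_NAMES:
        out[f"gldm_{name}"] = gd[name]

    nt = _ngtdm_features(gray, ng)
    for name in NGTDM_NAMES:
        out[f"ngtdm_{name}"] = nt[name]
    return out
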