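"""Image transform bank: identity, single-level undecimated Haar wavelet
sub-bands, Laplacian-of-Gaussian at several scales, gradient magnitude,
simple intensity maps and local-binary-pattern style counts.

The default bank has 20 members; it is configuration-driven so the count is
adjustable.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["TRANSFORMS", "apply_transform", "default_bank"]

_SQRT2 = float(np.sqrt(2.0))
_LOW = np.array([1.0, 1.0]) / _SQRT2
_HIGH = np.array([1.0, -1.0]) / _SQRT2


def _haar(vol: np.ndarray, bands: str) -> np.ndarray:
    out = vol
    for axis, b in enumerate(bands):
        w = _LOW if b == "L" else _HIGH
        out = ndimage.correlate1d(out, w, axis=axis, mode="nearest", origin=-1)
    return out


def _log(vol: np.ndarray, spacing, sigma_mm: float) -> np.ndarray:
    sig = [sigma_mm / s for s in spacing]
    return ndimage.gaussian_laplace(vol, sigma=sig, mode="nearest")


def _gradient_magnitude(vol: np.ndarray, spacing) -> np.ndarray:
    grads = np.gradient(vol, *spacing)
    return np.sqrt(sum(g**2 for g in grads))


def _neighbor_less_count(vol: np.ndarray, offsets) -> np.ndarray:
    """Count of neighbours with a strictly smaller value (LBP-style code)."""
    pad = np.pad(vol, 1, mode="edge")
    count = np.zeros(vol.shape)
    sl = tuple(slice(1, 1 + s) for s in vol.shape)
    for off in offsets:
        shifted = pad[tuple(slice(1 + o, 1 + o + s) for o, s in zip(off, vol.shape))]
        count += shifted < pad[sl]
    return count


_OFF26 = [
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]
_OFF6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def _safe_exp(vol: np.ndarray) -> np.ndarray:
    scale = np.abs(vol).max()
    return np.exp(vol / scale) if scale > 0 else np.ones_like(vol)


TRANSFORMS = {
    "original": lambda v, sp: v,
    "gradient": _gradient_magnitude,
    "square": lambda v, sp: v**2,
    "squareroot": lambda v, sp: np.sign(v) * np.sqrt(np.abs(v)),
    "logarithm": lambda v, sp: np.sign(v) * np.log1p(np.abs(v)),
    "exponential": lambda v, sp: _safe_exp(v),
    "lbp_26": lambda v, sp: _neighbor_less_count(v, _OFF26),
    "lbp_6": lambda v, sp: _neighbor_less_count(v, _OFF6),
}
for _bands in ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"):
    TRANSFORMS[f"wavelet_{_bands}"] = (
        lambda v, sp, b=_bands: _haar(v, b)
    )
for _s in (1, 2, 3, 4, 5):
    TRANSFORMS[f"log_sigma_{_s}_0_mm_3D"] = (
        lambda v, sp, s=_s: _log(v, sp, float(s))
    )


def apply_transform(name: str, vol: np.ndarray, spacing) -> np.ndarray:
    if name not in TRANSFORMS:
        raise KeyError(f"unknown transform {name!r}; available: {sorted(TRANSFORMS)}")
    return TRANSFORMS[name](np.asarray(vol, dtype=float), spacing)


def default_bank() -> list[str]:
    """Default 20-transform bank: identity, 8 wavelet sub-bands, 5 LoG scales,
    gradient, square, square-root, logarithm, exponential and one LBP variant
    (a second variant, lbp_6, is available in the registry)."""
    return (
        ["original"]
        + [f"wavelet_{b}" for b in ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")]
        + [f"log_sigma_{s}_0_mm_3D" for s in (1, 2, 3, 4, 5)]
        + ["gradient", "square", "squareroot", "logarithm", "exponential", "lbp_26"]
    )
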