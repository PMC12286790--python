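"""Synthetic phantom cohorts with the statistical structure the analysis
assumes: ellipsoidal tumors containing contiguous signal subpopulations
("habitats"), APTw/ADC volumes, optional z-spectrum stacks, planted habitat
ground truth, two-reader ROI measurements and skewed clinical covariates.

Default calibration targets (medians / class means):

* whole-tumor APTw: ~2.31% (negative class) vs ~4.36% (positive class);
* ADC anti-correlated with APTw: ~1.74 vs ~0.83 (1e-3 mm^2/s);
* CA125 medians 22.5 vs 44.45 U/mL, tumor size 31 vs 42.5 mm, and the
  remaining covariates near their published medians/IQRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .aptw import APTwMap, ROIMeasurement, ZSpectrumStack, measure_three_roi_mean

__all__ = [
    "CohortConfig",
    "ClinicalRecord",
    "PhantomPatient",
    "generate_cohort",
    "generate_texture_phantom",
    "simulate_two_readers",
    "cohort_table",
    "perturb_feature_table",
    "DEFAULT_CLINICAL_PARAMS",
]

# log-normal is parameterized by the median (= exp(mu)) and sigma, where sigma
# is solved from the target IQR ratio: Q3/Q1 = exp(1.349 * sigma)
DEFAULT_CLINICAL_PARAMS: dict[str, dict[str, float]] = {
    "ca125": {"median_neg": 22.50, "median_pos": 44.45, "sigma_neg": 0.347, "sigma_pos": 0.754},
    "tumor_size": {"median_neg": 31.0, "median_pos": 42.5, "sigma_neg": 0.134, "sigma_pos": 0.415},
    "age": {"median_neg": 47.0, "median_pos": 51.0, "sigma_neg": 0.218, "sigma_pos": 0.239},
    "bmi": {"median_neg": 24.96, "median_pos": 25.27, "sigma_neg": 0.126, "sigma_pos": 0.132},
    "menopause": {"p_neg": 0.419, "p_pos": 0.52},
    "figo_gt2": {"p_neg": 0.068, "p_pos": 0.14},
}


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 124
    prevalence_pos: float = 50 / 124
    seed: int = 0
    grid_shape: tuple[int, int, int] = (28, 28, 20)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_habitat_sources: int = 3
    #: APTw percent-units separation of the class base levels
    effect_size_aptw: float = 1.75
    #: percent-units spacing between adjacent habitat levels
    habitat_spread: float = 1.6
    #: extra share of tumor volume pulled into the highest-APTw habitat for
    #: positive patients (drives the habitat-3 fraction signal)
    h3_bias_pos: float = 0.55
    #: deterministic per-habitat texture amplitude, as a fraction of the
    #: habitat-level alternating-amplitude pattern (0 disables texture)
    texture_amp_frac: float = 0.5
    #: carve a 1-voxel non-tumour septum between planted habitats so that
    #: sliding-window features never mix subpopulations
    habitat_septum: bool = True
    noise_sd: float = 0.25
    reader_noise_sd: float = 0.15
    smooth_sigma_vox: float = 0.5
    #: between-patient SD of the APTw base level (percent units); large enough
    #: that single-parameter discrimination is imperfect, as in real cohorts
    between_patient_sd: float = 1.35
    adc_intercept: float = 2.765
    adc_slope: float = 0.444
    adc_noise_sd: float = 0.04
    necrosis_fraction: float = 0.03
    make_zspectra: bool = False
    zspectrum_offsets: tuple[float, ...] = tuple(np.round(np.arange(-6.0, 6.5, 0.5), 2))
    #: scale of every clinical class effect; 0 plus effect_size_aptw=0 and
    #: h3_bias_pos=0 gives the null configuration (label independent of data)
    clinical_effect_scale: float = 1.0
    clinical_params: dict = field(default_factory=lambda: DEFAULT_CLINICAL_PARAMS)

    def __post_init__(self):
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        if not 0.0 < self.prevalence_pos < 1.0:
            raise ValueError("prevalence_pos must lie in (0, 1)")
        if any(s < 9 for s in self.grid_shape):
            raise ValueError(
                f"grid_shape {self.grid_shape} too small: every axis must be >= 9 "
                "so the 3x3x3 sliding window fits inside the tumor"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_habitat_sources < 1:
            raise ValueError("need at least one habitat source")

    def null(self) -> "CohortConfig":
        """Copy of this config with all label-linked effects switched off."""
        return replace(self, effect_size_aptw=0.0, h3_bias_pos=0.0, clinical_effect_scale=0.0)


@dataclass(frozen=True)
class ClinicalRecord:
    age: float
    bmi: float
    ca125: float
    tumor_size: float
    menopause: int
    figo_gt2: int

    def __post_init__(self):
        if min(self.age, self.bmi, self.ca125, self.tumor_size) <= 0:
            raise ValueError("clinical covariates must be positive")
        if self.tumor_size < 10:
            raise ValueError("tumor_size must be >= 10 mm (inclusion criterion)")


@dataclass
class PhantomPatient:
    patient_id: str
    lvsi_label: int
    volume_aptw: np.ndarray
    volume_adc: np.ndarray
    mask: np.ndarray
    necrosis_mask: np.ndarray
    true_habitat_map: np.ndarray
    clinical: ClinicalRecord
    zspectrum: ZSpectrumStack | None = None
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self):
        if not self.mask.any():
            raise ValueError("mask must be nonempty")
        shapes = {self.volume_aptw.shape, self.volume_adc.shape, self.mask.shape,
                  self.true_habitat_map.shape}
        if len(shapes) != 1:
            raise ValueError("all volumes must share one shape")

    @property
    def aptw_map(self) -> APTwMap:
        return APTwMap(values=self.volume_aptw, mask=self.mask)

    @property
    def adc_map(self) -> APTwMap:
        return APTwMap(values=self.volume_adc, mask=self.mask)


# ---------------------------------------------------------------------------
# generation internals
# ---------------------------------------------------------------------------


def _ellipsoid_mask(shape, semi_axes, center) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return q <= 1.0


def _lognormal(rng, median: float, sigma: float) -> float:
    return float(median * np.exp(sigma * rng.standard_normal()))


def _sample_clinical(rng, positive: bool, params: dict, effect_scale: float) -> ClinicalRecord:
    def med_sig(name):
        p = params[name]
        if positive:
            # shrink the class contrast toward the negative-class value as
            # effect_scale -> 0 (log-scale interpolation keeps positivity)
            log_med = (1 - effect_scale) * np.log(p["median_neg"]) + effect_scale * np.log(
                p["median_pos"]
            )
            sig = (1 - effect_scale) * p["sigma_neg"] + effect_scale * p["sigma_pos"]
            return float(np.exp(log_med)), sig
        return p["median_neg"], p["sigma_neg"]

    def bern(name):
        p = params[name]
        prob = p["p_neg"] + (p["p_pos"] - p["p_neg"]) * effect_scale if positive else p["p_neg"]
        return int(rng.random() < prob)

    ca125 = _lognormal(rng, *med_sig("ca125"))
    size = _lognormal(rng, *med_sig("tumor_size"))
    age = _lognormal(rng, *med_sig("age"))
    bmi = _lognormal(rng, *med_sig("bmi"))
    return ClinicalRecord(
        age=max(age, 20.0),
        bmi=max(bmi, 15.0),
        ca125=max(ca125, 1.0),
        tumor_size=min(max(size, 12.0), 46.0),
        menopause=bern("menopause"),
        figo_gt2=bern("figo_gt2"),
    )


def _plant_habitats(rng, mask, k: int, h_top_weight: float, septum: bool = True) -> np.ndarray:
    """Weighted-Voronoi partition of the mask into k contiguous subregions.

    ``h_top_weight`` > 1 enlarges the highest-numbered habitat.
    """
    coords = np.argwhere(mask)
    n = coords.shape[0]
    if n < k:
        raise ValueError("mask smaller than number of habitat sources")
    # farthest-point seed placement -> roughly even, contiguous cells
    seeds = [coords[rng.integers(n)].astype(float)]
    for _ in range(k - 1):
        d = np.min(
            np.linalg.norm(coords[:, None, :] - np.asarray(seeds)[None, :, :], axis=2),
            axis=1,
        )
        seeds.append(coords[int(np.argmax(d))].astype(float))
    seeds = np.asarray(seeds)
    rng.shuffle(seeds)  # decouple habitat index from placement order
    weights = np.ones(k)
    weights[-1] = h_top_weight
    d = np.linalg.norm(coords[:, None, :] - seeds[None, :, :], axis=2) / weights[None, :]
    assign = np.argmin(d, axis=1) + 1  # habitats 1..k
    labels = np.zeros(mask.shape, dtype=np.uint8)
    labels[tuple(coords.T)] = assign
    if septum:
        # carve a 1-voxel inter-habitat septum out of the tumour so the
        # subpopulations are separated by non-tumour tissue
        border = np.zeros(mask.shape, dtype=bool)
        for ax in range(3):
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[ax] = slice(0, -1)
            sl_b[ax] = slice(1, None)
            diff = (
                (labels[tuple(sl_a)] != labels[tuple(sl_b)])
                & (labels[tuple(sl_a)] > 0)
                & (labels[tuple(sl_b)] > 0)
            )
            border[tuple(sl_a)] |= diff
        labels[border] = 0
    return labels


def _make_zspectrum(aptw_values, mask, offsets, rng) -> ZSpectrumStack:
    """Lorentzian direct-water saturation plus an amide dip at +3.5 ppm whose
    amplitude equals the planted APTw fraction, so MTR asymmetry recovers the
    planted field exactly."""
    offsets = np.asarray(offsets, dtype=float)
    s0 = np.full(mask.shape, 1000.0)
    s0 *= 1.0 + 0.02 * rng.standard_normal(mask.shape)
    amide_amp = np.clip(aptw_values / 100.0, 0.0, 0.5)
    sig = np.empty((offsets.size,) + mask.shape, dtype=float)
    for i, w in enumerate(offsets):
        direct = 0.85 / (1.0 + (w / 1.2) ** 2)
        amide = amide_amp * np.exp(-((w - 3.5) ** 2) / (2 * 0.4**2))
        sig[i] = s0 * np.clip(1.0 - direct - amide, 0.0, None)
    return ZSpectrumStack(signals=sig, offsets=offsets, s0=s0)


def _generate_patient(cfg: CohortConfig, rng, pid: str, label: int) -> PhantomPatient:
    shape = cfg.grid_shape
    spacing = np.asarray(cfg.voxel_spacing, dtype=float)
    clin = _sample_clinical(rng, bool(label), cfg.clinical_params, cfg.clinical_effect_scale)

    # geometry: largest semi-axis from the clinical tumour size, clipped so the
    # ellipsoid keeps a 2-voxel margin inside the grid
    a_vox = clin.tumor_size / 2.0 / spacing[0]
    max_a = (shape[0] - 5) / 2.0
    a_vox = min(a_vox, max_a)
    b_vox = min(a_vox * rng.uniform(0.72, 0.95), (shape[1] - 5) / 2.0)
    c_vox = min(a_vox * rng.uniform(0.55, 0.85), (shape[2] - 5) / 2.0)
    center = tuple(s / 2.0 + rng.uniform(-0.5, 0.5) for s in shape)
    mask = _ellipsoid_mask(shape, (a_vox, b_vox, c_vox), center)
    # measured convention: tumour size = largest mask axis extent in mm
    extent = [(np.ptp(np.flatnonzero(mask.any(axis=tuple(set(range(3)) - {ax})))) + 1)
              * spacing[ax] for ax in range(3)]
    clin = ClinicalRecord(
        age=clin.age, bmi=clin.bmi, ca125=clin.ca125,
        tumor_size=float(max(extent)), menopause=clin.menopause, figo_gt2=clin.figo_gt2,
    )

    k = cfg.n_habitat_sources
    top_w = 1.0 + (cfg.h3_bias_pos if label else 0.0)
    habitats = _plant_habitats(rng, mask, k, top_w, septum=cfg.habitat_septum)
    if cfg.habitat_septum:
        mask = habitats > 0  # septum voxels are non-tumour tissue

    base = 2.31 + (cfg.effect_size_aptw if label else 0.0)
    base += cfg.between_patient_sd * rng.standard_normal()
    levels = base + (np.arange(1, k + 1) - (k + 1) / 2.0) * cfg.habitat_spread
    aptw = np.zeros(shape, dtype=float)
    checker = _checker(shape)
    amps = cfg.texture_amp_frac * _habitat_amplitudes(k, cfg.habitat_spread)
    for h in range(1, k + 1):
        sel = habitats == h
        aptw[sel] = levels[h - 1] + amps[h - 1] * checker[sel]

    necrosis = np.zeros(shape, dtype=bool)
    if cfg.necrosis_fraction > 0:
        r = (3 * cfg.necrosis_fraction * mask.sum() / (4 * np.pi)) ** (1 / 3)
        nc = np.argwhere(mask)[rng.integers(mask.sum())].astype(float)
        necrosis = _ellipsoid_mask(shape, (r, r, r), tuple(nc)) & mask
        aptw[necrosis] = levels[0] - 0.5  # hypointense core

    if cfg.smooth_sigma_vox > 0:
        aptw[~mask] = base  # neutral background: no edge bias from smoothing
        aptw = ndimage.gaussian_filter(aptw, cfg.smooth_sigma_vox)
    aptw += cfg.noise_sd * rng.standard_normal(shape)
    aptw[~mask] = 0.0

    adc = cfg.adc_intercept - cfg.adc_slope * aptw
    adc += cfg.adc_noise_sd * rng.standard_normal(shape)
    adc[~mask] = 0.0

    zspec = None
    if cfg.make_zspectra:
        zspec = _make_zspectrum(aptw, mask, cfg.zspectrum_offsets, rng)

    return PhantomPatient(
        patient_id=pid,
        lvsi_label=int(label),
        volume_aptw=aptw,
        volume_adc=adc,
        mask=mask,
        necrosis_mask=necrosis,
        true_habitat_map=habitats,
        clinical=clin,
        zspectrum=zspec,
        spacing=tuple(spacing),
    )


def _checker(shape) -> np.ndarray:
    """Period-2 3D checkerboard; its 3x3x3-window statistics are essentially
    phase-invariant, so it serves as a deterministic texture carrier."""
    x, y, z = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    return (-1.0) ** (x + y + z)


def _habitat_amplitudes(k: int, delta: float) -> np.ndarray:
    """Texture amplitudes alternating low/high so that habitats adjacent in
    signal level remain well separated in texture space."""
    amps = np.empty(k)
    for h in range(1, k + 1):
        amps[h - 1] = 0.3 + (1.2 if h % 2 == 0 else 0.0) + 0.3 * ((h - 1) // 2)
    return amps * delta


def generate_texture_phantom(
    k: int,
    delta: float = 2.0,
    seed: int = 0,
    radius: int = 8,
    noise_sd_frac: float = 0.08,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Phantom with k spatially separated ball-shaped subpopulations, each
    carrying a distinct mean level and a distinct deterministic texture
    amplitude. Returns (volume, mask, habitat ground truth).

    Designed for planted-partition recovery studies of the habitat stage:
    the subpopulations are separated by background so sliding-window features
    never mix habitats.
    """
    if k < 2:
        raise ValueError("need at least 2 subpopulations")
    rng = np.random.default_rng(seed)
    step = 2 * radius + 4
    shape = (k * step + 4, 2 * radius + 8, 2 * radius + 8)
    checker = _checker(shape)
    amps = _habitat_amplitudes(k, delta)
    mask = np.zeros(shape, dtype=bool)
    hab = np.zeros(shape, dtype=np.uint8)
    vol = np.zeros(shape)
    for h in range(1, k + 1):
        c = ((h - 0.5) * step + 2, shape[1] / 2, shape[2] / 2)
        ball = _ellipsoid_mask(shape, (radius, radius, radius), c)
        mask |= ball
        hab[ball] = h
        vol[ball] = (h * delta + amps[h - 1] * checker)[ball]
    vol += noise_sd_frac * delta * rng.standard_normal(shape)
    vol[~mask] = 0.0
    return vol, mask, hab


def generate_cohort(config: CohortConfig) -> list[PhantomPatient]:
    """Deterministic phantom cohort; class counts match the configured
    prevalence within rounding."""
    n_pos = int(round(config.n_patients * config.prevalence_pos))
    n_pos = min(max(n_pos, 1), config.n_patients - 1)
    labels = np.r_[np.ones(n_pos, dtype=int), np.zeros(config.n_patients - n_pos, dtype=int)]
    root = np.random.default_rng(config.seed)
    root.shuffle(labels)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    return [
        _generate_patient(config, np.random.default_rng(streams[i]), f"P{i:04d}", labels[i])
        for i in range(config.n_patients)
    ]


def cohort_table(patients: list[PhantomPatient]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": p.patient_id,
            "lvsi": p.lvsi_label,
            "age": p.clinical.age,
            "bmi": p.clinical.bmi,
            "ca125": p.clinical.ca125,
            "tumor_size": p.clinical.tumor_size,
            "menopause": p.clinical.menopause,
            "figo_gt2": p.clinical.figo_gt2,
        }
        for p in patients
    ]
    return pd.DataFrame(rows).set_index("patient_id")


# ---------------------------------------------------------------------------
# reader simulation
# ---------------------------------------------------------------------------


def simulate_two_readers(
    patient: PhantomPatient,
    reader_noise_sd: float = 0.15,
    seed: int = 0,
    roi_radius_mm: float = 2.0,
) -> tuple[dict[str, ROIMeasurement], dict[str, ROIMeasurement]]:
    """Two independent readers each place three circular ROIs (avoiding the
    planted necrosis) and report per-ROI APTw and ADC means perturbed by
    independent reader noise."""
    readers = []
    rng = np.random.default_rng(seed)
    for _reader in range(2):
        out = {}
        for name, vol in (("aptw", patient.volume_aptw), ("adc", patient.volume_adc)):
            m = measure_three_roi_mean(
                APTwMap(values=vol, mask=patient.mask),
                exclusion_mask=patient.necrosis_mask,
                roi_radius_mm=roi_radius_mm,
                spacing=patient.spacing,
            )
            scale = reader_noise_sd if name == "aptw" else reader_noise_sd * 0.2
            noisy = m.per_roi_means + scale * rng.standard_normal(3)
            out[name] = ROIMeasurement(
                roi_centers=m.roi_centers, roi_radius_mm=m.roi_radius_mm, per_roi_means=noisy
            )
        readers.append(out)
    return readers[0], readers[1]


def perturb_feature_table(table: pd.DataFrame, rel_sd: float, seed: int) -> pd.DataFrame:
    """Second-reader surrogate for a feature table: add zero-mean noise scaled
    per feature by ``rel_sd`` times that feature's between-patient SD."""
    rng = np.random.default_rng(seed)
    sd = table.std(axis=0).to_numpy()
    noise = rng.standard_normal(table.shape) * sd[None, :] * rel_sd
    return table + noise
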