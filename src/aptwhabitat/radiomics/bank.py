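"""Per-habitat feature extraction over the transform bank.

Column naming is ``{transform}_{family}_{name}_h{habitat}`` (shape features
use the ``shape`` family under the ``original`` transform and are computed
once per habitat, since transforms alter intensities, not geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .firstorder import firstorder_features
from .shape import shape_features
from .texture import texture_features
from .transforms import apply_transform, default_bank

__all__ = ["FeatureBankConfig", "region_feature_vector", "extract_feature_table"]


@dataclass(frozen=True)
class FeatureBankConfig:
    transforms: tuple[str, ...] = field(default_factory=lambda: tuple(default_bank()))
    bin_width: float = 0.1
    gray_levels: int = 16
    aggregation: str = "direction_average"

    def __post_init__(self):
        if "original" not in self.transforms:
            raise ValueError("the identity ('original') transform must be present")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.gray_levels < 2:
            raise ValueError("need at least 2 gray levels")

    @property
    def columns_per_habitat(self) -> int:
        return 14 + len(self.transforms) * 93


def region_feature_vector(
    volume: np.ndarray,
    region_mask: np.ndarray,
    spacing,
    config: FeatureBankConfig,
    habitat: int,
    transformed: dict[str, np.ndarray] | None = None,
) -> dict[str, float]:
    """All features of one habitat region of one patient volume."""
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("empty habitat region")
    coords = np.argwhere(region_mask)
    voxel_volume = float(np.prod(spacing))
    out: dict[str, float] = {}
    for name, val in shape_features(region_mask, spacing).items():
        out[f"original_shape_{name}_h{habitat}"] = val
    for t in config.transforms:
        if transformed is not None and t in transformed:
            tvol = transformed[t]
        else:
            tvol = apply_transform(t, volume, spacing)
            if transformed is not None:
                transformed[t] = tvol
        vals = tvol[region_mask]
        for name, v in firstorder_features(
            vals, bin_width=config.bin_width, voxel_volume=voxel_volume
        ).items():
            out[f"{t}_firstorder_{name}_h{habitat}"] = v
        for name, v in texture_features(
            vals, coords, gray_levels=config.gray_levels
        ).items():
            out[f"{t}_{name}_h{habitat}"] = v
    return out


def extract_feature_table(
    volumes: dict[str, np.ndarray],
    habitat_labels: dict[str, np.ndarray],
    spacings: dict[str, tuple],
    config: FeatureBankConfig | None = None,
    n_habitats: int = 3,
) -> tuple[pd.DataFrame, list[str]]:
    """Feature table (patients x named features) across habitats 1..n_habitats.

    A habitat absent in some patient yields NaN for its columns and flags the
    patient. Returns (table, flagged_patient_ids).
    """
    config = config or FeatureBankConfig()
    rows: dict[str, dict[str, float]] = {}
    flagged: list[str] = []
    for pid, vol in volumes.items():
        labels = habitat_labels[pid]
        if labels.shape != vol.shape:
            raise ValueError(f"patient {pid}: habitat map not aligned with volume")
        spacing = spacings[pid]
        transformed: dict[str, np.ndarray] = {}
        row: dict[str, float] = {}
        for h in range(1, n_habitats + 1):
            region = labels == h
            if not region.any():
                flagged.append(pid)
                continue
            row.update(
                region_feature_vector(vol, region, spacing, config, h, transformed)
            )
        rows[pid] = row
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    table.index.name = "patient_id"
    return table, flagged
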