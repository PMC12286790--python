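"""Readers/writers for the pipeline's on-disk artifacts.

Volumes: NIfTI-1 (affine carried through untouched; masks and habitat labels
as unsigned 8-bit). Tables: comma-separated UTF-8 CSV with mandatory header
and "." decimal. Configs and manifests: JSON. Every writer has a matching
reader and round-trips bit-exactly for the numeric payload.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(path, data: np.ndarray, spacing, dtype=None) -> Path:
    path = Path(path)
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr, _affine(spacing))
    nib.save(img, str(path))
    return path


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def write_table(path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, encoding="utf-8")
    return path


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, index_col=index_col, encoding="utf-8")


def write_json(path, obj) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))
    return path


def read_json(path):
    return json.loads(Path(path).read_text())


def checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(run_dir, inputs: dict[str, Path], seed: int, stages: list[str]) -> Path:
    manifest = {
        "seed": seed,
        "stages": stages,
        "inputs": {k: {"path": str(p), "sha256": checksum(p)} for k, p in inputs.items()},
    }
    return write_json(Path(run_dir) / "manifest.json", manifest)
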