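"""File I/O helpers: NIfTI images, sidecar value lists, atomic writes."""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_sidecar_values",
    "load_sidecar_values",
    "atomic_write_text",
    "save_json",
    "save_csv",
    "curve_to_csv",
]


def save_nifti(path: str | Path, data: np.ndarray,
               spacing: tuple[float, ...] | None = None) -> Path:
    """Write an array as NIfTI-1 with voxel spacing on the affine diagonal."""
    path = Path(path)
    affine = np.eye(4)
    if spacing is not None:
        for i, s in enumerate(spacing[:3]):
            affine[i, i] = s
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    # temp name keeps the .nii suffix so nibabel can infer the format
    tmp = path.parent / f".{path.stem}.tmp{path.suffix}"
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(tmp))
    os.replace(tmp, path)
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    """Load a NIfTI image; returns (array, spacing) and validates the header."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    except Exception as exc:
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    return data, zooms


def save_sidecar_values(path: str | Path, values) -> Path:
    """One value per line (FSL-style bval / TI-list sidecar)."""
    text = "\n".join(f"{v:g}" for v in values) + "\n"
    return atomic_write_text(path, text)


def load_sidecar_values(path: str | Path) -> np.ndarray:
    return np.loadtxt(str(path), ndmin=1)


def atomic_write_text(path: str | Path, text: str) -> Path:
    """Write text to ``path`` via a temp file + rename (no partial files)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)
    return path


def _json_default(o):
    if isinstance(o, np.generic):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def save_json(path: str | Path, obj) -> Path:
    text = json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n"
    return atomic_write_text(path, text)


def save_csv(path: str | Path, df: pd.DataFrame) -> Path:
    return atomic_write_text(path, df.to_csv(index=False))


def curve_to_csv(path: str | Path, times_min: np.ndarray,
                 concentration_mM: np.ndarray) -> Path:
    df = pd.DataFrame({"time_min": times_min, "concentration_mM": concentration_mM})
    return save_csv(path, df)
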