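"""NIfTI-1 volume I/O helpers (float32, affine-preserving)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["write_nifti", "read_nifti"]


def write_nifti(volume: np.ndarray, affine: np.ndarray, path) -> Path:
    """Write a volume as float32 NIfTI-1; complex volumes are not supported."""
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4) or not np.all(np.isfinite(affine)):
        raise ValueError("affine must be a finite 4x4 matrix")
    path = Path(path)
    try:
        img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
        nib.save(img, str(path))
    except Exception as exc:  # surface the path in the error
        raise OSError(f"failed to write NIfTI volume to {path}: {exc}") from exc
    return path


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns ``(data, affine)`` with float data."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NIfTI file not found: {path}")
    try:
        img = nib.load(str(path))
        return np.asanyarray(img.dataobj).astype(np.float32), img.affine
    except Exception as exc:
        raise OSError(f"failed to read NIfTI volume from {path}: {exc}") from exc
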