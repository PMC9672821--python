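"""Volume and table I/O.

All volumes travel as NIfTI-1 with an axis-aligned affine built from the voxel
spacing; 4D series additionally carry the frame interval (s) in the temporal
zoom.  Binary masks are stored as unsigned bytes with values {0, 1}.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "sha256_file",
    "write_json",
    "read_json",
]


def write_volume(
    path: str | Path,
    values: np.ndarray,
    voxel_spacing: tuple[float, float, float],
    dt: float | None = None,
) -> Path:
    """Write a 3D or 4D scalar grid as NIfTI-1.

    Parameters
    ----------
    values
        ``(X, Y, Z)`` or ``(X, Y, Z, T)`` array.
    voxel_spacing
        In-plane and through-plane spacing in mm.
    dt
        Frame interval in seconds; required for 4D data.
    """
    values = np.asarray(values)
    if values.ndim == 4 and (dt is None or dt <= 0):
        raise ValueError("4D series require a positive temporal spacing dt")
    affine = np.diag([*voxel_spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine)
    if values.ndim == 4:
        img.header.set_zooms((*voxel_spacing, float(dt)))
        img.header.set_xyzt_units(xyz="mm", t="sec")
    else:
        img.header.set_xyzt_units(xyz="mm")
    path = Path(path)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, ...], float | None]:
    """Read a NIfTI volume.

    Returns ``(values, voxel_spacing, dt)``; ``dt`` is ``None`` for 3D input.
    4D input without a stored frame interval is rejected — write the series
    through :func:`write_volume` (or set pixdim[4]) so the time axis is scaled.
    """
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()
    spacing = tuple(float(z) for z in zooms[:3])
    if values.ndim == 4:
        if len(zooms) < 4 or zooms[3] <= 0:
            raise ValueError(
                f"{path}: 4D series carries no temporal spacing; "
                "store the frame interval in pixdim[4] (seconds)"
            )
        return values, spacing, float(zooms[3])
    return values, spacing, None


def write_mask(
    path: str | Path, mask: np.ndarray, voxel_spacing: tuple[float, float, float]
) -> Path:
    """Write a binary mask as uint8 NIfTI with values {0, 1}."""
    mask = np.asarray(mask).astype(bool)
    affine = np.diag([*voxel_spacing, 1.0])
    img = nib.Nifti1Image(mask.astype(np.uint8), affine)
    img.header.set_xyzt_units(xyz="mm")
    path = Path(path)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(path: str | Path, obj: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
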