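"""File I/O: NIfTI-1 volumes, CSV tables, YAML configs.

Volumes are written RAS-aligned with a diagonal affine (voxel spacing on
the diagonal, grid origin in the translation column), so the package's
axis-aligned :class:`~phantomac.grids.VoxelGrid` round-trips exactly to
float32 precision.  Only axis-aligned affines are accepted on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .grids import VoxelGrid


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    for a in range(3):
        aff[a, a] = grid.spacing[a]
        aff[a, 3] = grid.origin[a]
    return aff


def write_volume(values: np.ndarray, grid: VoxelGrid, path, description: str = ""):
    """Write a volume as NIfTI-1 (float32, or the integer dtype given)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if np.issubdtype(values.dtype, np.integer) or values.dtype == bool:
        data = np.asarray(values, dtype=np.uint8)
    else:
        data = np.asarray(values, dtype=np.float32)
    img = nib.Nifti1Image(data, _affine(grid))
    img.header.set_zooms(grid.spacing)
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def read_volume(path):
    """Read a NIfTI-1 volume; returns ``(values, grid, description)``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-5):
        raise ValueError("only axis-aligned (diagonal-affine) volumes are supported")
    spacing = tuple(float(aff[a, a]) for a in range(3))
    origin = tuple(float(aff[a, 3]) for a in range(3))
    data = np.asanyarray(img.dataobj)
    grid = VoxelGrid(data.shape, spacing, origin)
    descrip = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="ignore")
    return data, grid, descrip


def save_sinogram(sino_values: np.ndarray, geometry_dict: dict, path):
    """Sinogram as .npy with a JSON geometry sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(str(path), sino_values)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(geometry_dict, fh, indent=2)


def load_sinogram(path):
    path = Path(path)
    values = np.load(str(path))
    with open(path.with_suffix(".json")) as fh:
        geometry = json.load(fh)
    return values, geometry


def save_config(config_dict: dict, path):
    with open(path, "w") as fh:
        yaml.safe_dump(config_dict, fh, sort_keys=True)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a config, embedded in output metadata."""
    canon = yaml.safe_dump(config_dict, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
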