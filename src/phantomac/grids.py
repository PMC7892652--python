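"""Metric voxel grids and grid-to-grid resampling.

Every volume in this package (labels, Dixon channels, CT, mu-maps,
reconstructions) lives on an axis-aligned :class:`VoxelGrid` in a
right-handed millimetre coordinate frame with z along the phantom /
scanner axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice on a metric coordinate frame.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z).
    spacing
        Voxel pitch in mm along (x, y, z); all entries must be positive.
    origin
        Physical position (mm) of the *center* of voxel (0, 0, 0).

    Notes
    -----
    Indexing is 0-based and a voxel owns the half-open box
    ``[center - spacing/2, center + spacing/2)``.
    """

    shape: tuple
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("grid shape, spacing and origin must be 3-vectors")
        if any(n < 1 for n in shape):
            raise ValueError("grid shape entries must be >= 1")
        if any(s <= 0 for s in spacing):
            raise ValueError("grid spacings must be > 0")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @classmethod
    def centered(cls, shape, spacing, z_min=None) -> "VoxelGrid":
        """Grid whose in-plane (x, y) field of view is centered on (0, 0).

        If ``z_min`` is given, the lower edge of the first slice sits at
        that z position; otherwise z is centered on 0 as well.
        """
        shape = tuple(int(n) for n in shape)
        spacing = tuple(float(s) for s in spacing)
        ox = -(shape[0] - 1) / 2.0 * spacing[0]
        oy = -(shape[1] - 1) / 2.0 * spacing[1]
        if z_min is None:
            oz = -(shape[2] - 1) / 2.0 * spacing[2]
        else:
            oz = float(z_min) + spacing[2] / 2.0
        return cls(shape, spacing, (ox, oy, oz))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (= cm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def lower_edges(self) -> tuple:
        return tuple(self.origin[a] - self.spacing[a] / 2.0 for a in range(3))

    @property
    def upper_edges(self) -> tuple:
        return tuple(
            self.origin[a] + (self.shape[a] - 0.5) * self.spacing[a] for a in range(3)
        )

    def covers_box(self, lo, hi) -> bool:
        """Whether the grid's physical extent contains the box [lo, hi] (mm)."""
        return all(
            self.lower_edges[a] <= lo[a] and self.upper_edges[a] >= hi[a]
            for a in range(3)
        )

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map physical points (..., 3) to fractional voxel indices."""
        pts = np.asarray(points_mm, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)


def resample(values: np.ndarray, src: VoxelGrid, dst: VoxelGrid,
             order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Resample a volume from one grid onto another.

    ``order=0`` gives nearest-neighbour (use for masks and labels, which
    must stay binary/integer); ``order=1`` trilinear (continuous maps).
    """
    if values.shape != src.shape:
        raise ValueError("volume shape does not match its grid")
    coords = []
    for a in range(3):
        c = (dst.axis_coords(a) - src.origin[a]) / src.spacing[a]
        coords.append(c)
    ix, iy, iz = np.meshgrid(*coords, indexing="ij", sparse=False)
    out = ndimage.map_coordinates(
        np.asarray(values, dtype=float),
        np.stack([ix, iy, iz]),
        order=order,
        mode="constant",
        cval=cval,
    )
    if np.issubdtype(values.dtype, np.bool_):
        return out > 0.5
    if np.issubdtype(values.dtype, np.integer) and order == 0:
        return np.rint(out).astype(values.dtype)
    return out.astype(np.float32)
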