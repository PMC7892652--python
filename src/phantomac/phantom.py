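"""Parametric model and voxelization of the water-fillable polymer phantom.

The phantom is a 3D-printed cylinder with a 6 mm polymer shell, closed by
a 10 mm top lid and a 5 mm bottom lid, enclosing a 24 cm diameter x
18.5 cm water compartment.  A Jaszczak-style array of solid polymer rods
(diameters 5-28 mm, 5 cm long) stands on the inner face of the bottom
lid, so the compartment has a homogeneous upper region and a
heterogeneous (rod) lower region.

Coordinates: right-handed, z along the cylinder axis, z = 0 at the outer
bottom face, all positions in mm (dimensions given in cm are converted
on construction).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .grids import VoxelGrid

#: voxel label codes
BACKGROUND, MATERIAL, WATER = 0, 1, 2


@dataclass(frozen=True)
class PhantomSpec:
    """Printed dimensions of the phantom, all lengths in cm (rods in mm).

    ``rod_diameters_mm`` and ``rod_centers_mm`` are parallel per-rod
    lists: rod *i* is the circle of diameter ``rod_diameters_mm[i]``
    centered at transaxial position ``rod_centers_mm[i]``.  Any layout
    may be supplied; the default is a sector layout (one diameter per
    60-degree sector, rods spaced one diameter edge-to-edge).
    """

    outer_length: float = 20.0
    outer_diameter: float = 25.2
    shell_thickness: float = 0.6
    top_lid_thickness: float = 1.0
    bottom_lid_thickness: float = 0.5
    rod_length: float = 5.0
    rod_diameters_mm: tuple = ()
    rod_centers_mm: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "rod_diameters_mm", tuple(float(d) for d in self.rod_diameters_mm))
        object.__setattr__(self, "rod_centers_mm",
                           tuple((float(x), float(y)) for x, y in self.rod_centers_mm))
        if len(self.rod_diameters_mm) != len(self.rod_centers_mm):
            raise ValueError("rod diameter and center lists must have equal length")
        if self.inner_diameter <= 0 or self.inner_length <= 0:
            raise ValueError("lids/shell thicker than the phantom itself")
        r_in = self.inner_diameter * 10.0 / 2.0
        for (x, y), d in zip(self.rod_centers_mm, self.rod_diameters_mm):
            if np.hypot(x, y) + d / 2.0 >= r_in:
                raise ValueError("rod does not lie strictly inside the inner compartment")
        for (c1, d1), (c2, d2) in itertools.combinations(
                zip(self.rod_centers_mm, self.rod_diameters_mm), 2):
            if np.hypot(c1[0] - c2[0], c1[1] - c2[1]) < (d1 + d2) / 2.0:
                raise ValueError("rods overlap")

    # -- derived dimensions (cm) -------------------------------------
    @property
    def inner_diameter(self) -> float:
        return self.outer_diameter - 2.0 * self.shell_thickness

    @property
    def inner_length(self) -> float:
        return self.outer_length - self.top_lid_thickness - self.bottom_lid_thickness

    # -- convenience in mm -------------------------------------------
    @property
    def outer_radius_mm(self) -> float:
        return self.outer_diameter * 10.0 / 2.0

    @property
    def inner_radius_mm(self) -> float:
        return self.inner_diameter * 10.0 / 2.0

    def bounding_box_mm(self):
        r = self.outer_radius_mm
        return (-r, -r, 0.0), (r, r, self.outer_length * 10.0)


def sector_rod_layout(diameters_mm=(5.0, 10.0, 13.0, 17.0, 22.0, 28.0),
                      inner_radius_mm: float = 120.0,
                      wall_clearance_mm: float = 5.0,
                      sector_margin_mm: float = 2.5,
                      r_start_mm: float = 35.0):
    """Jaszczak-style sector layout for the rod array.

    One 60-degree sector per rod diameter; within a sector the rods sit
    on a square lattice aligned with the sector bisector, center pitch
    twice the diameter, i.e. one diameter edge-to-edge.  Rods keep
    ``wall_clearance_mm`` to the shell and ``sector_margin_mm`` to the
    sector boundaries (so rods of neighbouring sectors cannot touch).

    Returns (centers, diameters) as parallel lists.
    """
    centers, diams = [], []
    n_sec = len(diameters_mm)
    for k, d in enumerate(diameters_mm):
        theta = np.deg2rad(k * 360.0 / n_sec)
        u = np.array([np.cos(theta), np.sin(theta)])       # sector bisector
        v = np.array([-np.sin(theta), np.cos(theta)])
        pitch = 2.0 * d
        half_wedge = np.pi / n_sec
        j = 0
        while True:
            s = r_start_mm + j * pitch
            if s > inner_radius_mm:
                break
            m_max = int(np.ceil(inner_radius_mm / pitch)) + 1
            for m in range(-m_max, m_max + 1):
                t = m * pitch
                pos = s * u + t * v
                r = np.hypot(pos[0], pos[1])
                if r + d / 2.0 > inner_radius_mm - wall_clearance_mm:
                    continue
                # distance to the two boundary half-planes of the wedge
                ang = np.arctan2(pos @ v, pos @ u)
                if abs(ang) >= half_wedge:
                    continue
                d_bound = r * np.sin(half_wedge - abs(ang))
                if d_bound < d / 2.0 + sector_margin_mm:
                    continue
                centers.append((pos[0], pos[1]))
                diams.append(d)
            j += 1
    return centers, diams


def default_phantom_spec() -> PhantomSpec:
    """The printed phantom: 25.2 cm outer diameter, 6 mm shell, 10/5 mm
    lids, 24 cm diameter x 18.5 cm inner compartment, and the six rod
    diameters {5, 10, 13, 17, 22, 28} mm in a sector layout."""
    centers, diams = sector_rod_layout()
    return PhantomSpec(rod_diameters_mm=tuple(diams), rod_centers_mm=tuple(centers))


@dataclass
class LabelVolume:
    """Voxelized phantom: integer labels plus anti-aliased fractions.

    ``labels`` holds {0 background, 1 material, 2 water} by majority
    vote over the subsamples; ``frac_material`` / ``frac_water`` are the
    per-voxel volume fractions the vote was based on (border voxels
    have fractional values and drive the partial-volume physics of the
    Dixon simulator).
    """

    grid: VoxelGrid
    labels: np.ndarray
    frac_material: np.ndarray
    frac_water: np.ndarray

    def __post_init__(self):
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid")
        vals = np.unique(self.labels)
        if not np.isin(vals, [BACKGROUND, MATERIAL, WATER]).all():
            raise ValueError("labels must be in {0, 1, 2}")

    @property
    def frac_background(self) -> np.ndarray:
        return 1.0 - self.frac_material - self.frac_water

    def label_volume_ml(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label)) * self.grid.voxel_volume_ml


def _plane_masks(spec: PhantomSpec, xs, ys):
    """In-plane (2D) membership masks at given x/y sample coordinates."""
    xx = xs[:, None]
    yy = ys[None, :]
    r2 = xx * xx + yy * yy
    in_outer = r2 <= spec.outer_radius_mm ** 2
    in_inner = r2 <= spec.inner_radius_mm ** 2
    rod = np.zeros_like(in_outer)
    for (cx, cy), d in zip(spec.rod_centers_mm, spec.rod_diameters_mm):
        rod |= (xx - cx) ** 2 + (yy - cy) ** 2 <= (d / 2.0) ** 2
    rod &= in_inner
    return in_outer, in_inner, rod


def rasterize(spec: PhantomSpec, grid: VoxelGrid, subsampling: int = 3) -> LabelVolume:
    """Voxelize the phantom on a grid with anti-aliased label fractions.

    Each voxel is probed at ``subsampling**3`` regularly spaced interior
    points; the label fractions are the fraction of points falling in
    material (shell, lids, rods) or water, and the stored label is the
    majority vote (ties resolved material > water > background, i.e.
    conservatively toward attenuating classes).

    Raises ``ValueError("grid too small")`` if the grid does not fully
    contain the phantom bounding box.
    """
    if subsampling < 1:
        raise ValueError("subsampling must be >= 1")
    lo, hi = spec.bounding_box_mm()
    if not grid.covers_box(lo, hi):
        raise ValueError("grid too small: it does not contain the phantom")

    nz = grid.shape[2]
    cnt_mat = np.zeros(grid.shape, dtype=np.uint16)
    cnt_wat = np.zeros(grid.shape, dtype=np.uint16)
    offsets = (np.arange(subsampling) + 0.5) / subsampling - 0.5

    L_out = spec.outer_length * 10.0
    z_bot = spec.bottom_lid_thickness * 10.0
    z_top = L_out - spec.top_lid_thickness * 10.0
    z_rod = z_bot + spec.rod_length * 10.0

    for ox in offsets:
        xs = grid.axis_coords(0) + ox * grid.spacing[0]
        for oy in offsets:
            ys = grid.axis_coords(1) + oy * grid.spacing[1]
            in_outer, in_inner, rod = _plane_masks(spec, xs, ys)
            shell_ring = in_outer & ~in_inner
            for oz in offsets:
                zs = grid.axis_coords(2) + oz * grid.spacing[2]
                in_phantom_z = (zs >= 0.0) & (zs < L_out)
                lid_z = in_phantom_z & ((zs < z_bot) | (zs >= z_top))
                inner_z = (zs >= z_bot) & (zs < z_top)
                rod_z = (zs >= z_bot) & (zs < z_rod)

                mat3 = shell_ring[:, :, None] & in_phantom_z[None, None, :]
                mat3 |= in_outer[:, :, None] & lid_z[None, None, :]
                rod3 = rod[:, :, None] & rod_z[None, None, :]
                mat3 |= rod3
                wat3 = in_inner[:, :, None] & inner_z[None, None, :] & ~rod3
                cnt_mat += mat3
                cnt_wat += wat3

    total = subsampling ** 3
    frac_mat = (cnt_mat / total).astype(np.float32)
    frac_wat = (cnt_wat / total).astype(np.float32)
    cnt_bg = total - cnt_mat.astype(np.int32) - cnt_wat.astype(np.int32)

    labels = np.zeros(grid.shape, dtype=np.uint8)
    is_mat = (cnt_mat >= cnt_wat) & (cnt_mat >= cnt_bg) & (cnt_mat > 0)
    is_wat = ~is_mat & (cnt_wat >= cnt_bg) & (cnt_wat > 0)
    labels[is_mat] = MATERIAL
    labels[is_wat] = WATER
    return LabelVolume(grid, labels, frac_mat, frac_wat)
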