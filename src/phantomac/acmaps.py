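"""Construction of the four competing attenuation maps.

From the Dixon volumes: a phantom-specific MR-AC (water 0.096 cm^-1,
polymer 0.1037 cm^-1), a NoWall variant (polymer set to zero, imitating
a conventional MRI-invisible housing), and an emulation of the vendor
whole-body Dixon MR-AC (everything soft tissue, 0.1 cm^-1, extent
overestimated by about one pixel).  From CT: the reference map via
bilinear HU -> mu scaling.

Segmentation follows the thresholding recipe: total-phantom support from
the opposed-phase image (> 100 a.u., morphological closing, largest
connected component, 1-voxel erosion); water compartment from the
fat-enhanced opposed-phase image (OP - 4 x filtered fat > 400 a.u.,
closing); housing material by mask subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .grids import VoxelGrid

#: linear attenuation coefficients at 511 keV, cm^-1
MU_WATER = 0.096
MU_MATERIAL = 0.1037
MU_SOFT_TISSUE = 0.1

#: default structuring elements: closing/erosion use the 6-connected
#: radius-1 cross; connected components use 26-connectivity
STRUCT_CROSS = ndimage.generate_binary_structure(3, 1)
STRUCT_FULL = ndimage.generate_binary_structure(3, 3)


def binary_closing(mask: np.ndarray, structure=None, iterations: int = 1) -> np.ndarray:
    """Morphological closing that is a true no-op on solid objects even
    at the array border (scipy's closing shrinks there because the
    dilation is clipped before the erosion)."""
    if iterations < 1:
        return mask.copy()
    structure = STRUCT_CROSS if structure is None else structure
    pad = iterations
    padded = np.pad(mask, pad, mode="constant", constant_values=False)
    dil = ndimage.binary_dilation(padded, structure=structure, iterations=iterations)
    ero = ndimage.binary_erosion(dil, structure=structure, iterations=iterations)
    return ero[tuple(slice(pad, -pad) for _ in range(mask.ndim))]


class ACMethod(str, Enum):
    CT_AC = "CT_AC"
    PHANTOM_MRAC = "PHANTOM_MRAC"
    STANDARD_MRAC = "STANDARD_MRAC"
    NOWALL_MRAC = "NOWALL_MRAC"
    GROUND_TRUTH = "GROUND_TRUTH"


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds (scanner arbitrary units), morphology radii (voxels)
    and attenuation coefficients (cm^-1) of the mu-map construction."""

    phantom_threshold: float = 100.0
    water_threshold: float = 400.0
    fat_floor: float = 10.0
    fat_sigma_px: float = 0.5
    fat_weight: float = 4.0
    erosion_radius: int = 1
    closing_radius: int = 1
    mu_water: float = MU_WATER
    mu_material: float = MU_MATERIAL
    mu_soft_tissue: float = MU_SOFT_TISSUE
    standard_dilation: int = 1

    def __post_init__(self):
        if min(self.phantom_threshold, self.water_threshold, self.fat_floor) < 0:
            raise ValueError("thresholds must be >= 0")
        if min(self.mu_water, self.mu_material, self.mu_soft_tissue) < 0:
            raise ValueError("attenuation coefficients must be >= 0")


@dataclass
class BinaryMask:
    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self):
        if self.values.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        self.values = self.values.astype(bool)

    @property
    def volume_ml(self) -> float:
        return float(np.count_nonzero(self.values)) * self.grid.voxel_volume_ml


@dataclass
class AttenuationMap:
    """Per-voxel linear attenuation coefficients (cm^-1, 511 keV)."""

    grid: VoxelGrid
    mu: np.ndarray
    method_tag: ACMethod

    def __post_init__(self):
        if self.mu.shape != self.grid.shape:
            raise ValueError("mu shape does not match grid")
        if not np.isfinite(self.mu).all() or np.any(self.mu < 0):
            raise ValueError("mu must be finite and >= 0")
        self.mu = self.mu.astype(np.float32)
        self.method_tag = ACMethod(self.method_tag)


@dataclass(frozen=True)
class BilinearScaling:
    """Bilinear conversion of CT numbers to 511 keV attenuation.

    Below ``break_hu`` (soft tissue/water regime) mu is proportional to
    HU + 1000 with the water slope, so 0 HU -> 0.096 cm^-1 and
    -1000 HU -> 0.  Above the break the standard 120 kVp bone slope
    applies, with the offset fixed by continuity at the break.
    """

    slope_low: float = 9.6e-5   # cm^-1 per HU
    break_hu: float = 47.0
    slope_high: float = 5.1e-5

    @property
    def mu_break(self) -> float:
        return self.slope_low * (self.break_hu + 1000.0)

    @property
    def offset_high(self) -> float:
        return self.mu_break - self.slope_high * (self.break_hu + 1000.0)

    def mu(self, hu):
        hu = np.asarray(hu, dtype=float)
        out = np.where(
            hu <= self.break_hu,
            self.slope_low * (hu + 1000.0),
            self.slope_high * (hu + 1000.0) + self.offset_high,
        )
        return np.maximum(out, 0.0)

    def hu_for_mu(self, mu: float) -> float:
        """Inverse mapping (round-trip oracle for the CT simulator)."""
        if mu <= self.mu_break:
            return mu / self.slope_low - 1000.0
        return (mu - self.offset_high) / self.slope_high - 1000.0


def total_phantom_mask(opposed_phase: np.ndarray, grid: VoxelGrid,
                       params: SegmentationParams | None = None) -> BinaryMask:
    """Support of the whole phantom from the opposed-phase image.

    threshold > ``phantom_threshold`` -> closing -> largest connected
    component -> isotropic 1-voxel erosion.  The low threshold makes the
    support overshoot the true surface by about a pixel; the erosion
    takes that back and drops FOV-edge artifacts.
    """
    params = params or SegmentationParams()
    thr = np.asarray(opposed_phase) > params.phantom_threshold
    if not thr.any():
        raise ValueError("empty phantom mask: no voxel above threshold")
    closed = binary_closing(thr, STRUCT_CROSS, params.closing_radius)
    lab, n = ndimage.label(closed, structure=STRUCT_FULL)
    if n == 0:
        raise ValueError("empty phantom mask: nothing left after closing")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    biggest = lab == (1 + int(np.argmax(sizes)))
    eroded = ndimage.binary_erosion(biggest, structure=STRUCT_CROSS,
                                    iterations=params.erosion_radius)
    if not eroded.any():
        raise ValueError("empty phantom mask: erosion removed everything")
    return BinaryMask(grid, eroded)


def water_mask(opposed_phase: np.ndarray, fat: np.ndarray, grid: VoxelGrid,
               params: SegmentationParams | None = None) -> BinaryMask:
    """Water-compartment mask from the fat-enhanced opposed-phase image.

    The filtered (sigma = 0.5 px), floored fat image is subtracted four
    times from the opposed-phase image; the partial-volume fat signal at
    the water/polymer border then pushes border voxels below the 400
    a.u. threshold, separating compartments that overlap in raw
    intensity.
    """
    params = params or SegmentationParams()
    if np.asarray(opposed_phase).shape != np.asarray(fat).shape:
        raise ValueError("opposed-phase and fat volumes must share one grid")
    f = ndimage.gaussian_filter(np.asarray(fat, dtype=float), params.fat_sigma_px)
    f[f < params.fat_floor] = 0.0
    enhanced = np.asarray(opposed_phase, dtype=float) - params.fat_weight * f
    mask = enhanced > params.water_threshold
    mask = binary_closing(mask, STRUCT_CROSS, params.closing_radius)
    return BinaryMask(grid, mask)


def material_mask(total: BinaryMask, water: BinaryMask) -> BinaryMask:
    """Housing material = total phantom support minus the water mask."""
    if total.grid != water.grid:
        raise ValueError("masks must share one grid")
    return BinaryMask(total.grid, total.values & ~water.values)


def build_phantom_mrac(total: BinaryMask, water: BinaryMask,
                       params: SegmentationParams | None = None) -> AttenuationMap:
    """Phantom-specific MR-AC: water 0.096, housing 0.1037 cm^-1."""
    params = params or SegmentationParams()
    mat = material_mask(total, water)
    mu = np.zeros(total.grid.shape, dtype=np.float32)
    mu[water.values] = params.mu_water
    mu[mat.values] = params.mu_material
    return AttenuationMap(total.grid, mu, ACMethod.PHANTOM_MRAC)


def build_nowall_mrac(total: BinaryMask, water: BinaryMask,
                      params: SegmentationParams | None = None) -> AttenuationMap:
    """Like the phantom MR-AC but the housing gets zero attenuation,
    imitating a conventional MRI-invisible phantom wall."""
    params = params or SegmentationParams()
    mu = np.zeros(total.grid.shape, dtype=np.float32)
    mu[water.values] = params.mu_water
    return AttenuationMap(total.grid, mu, ACMethod.NOWALL_MRAC)


def build_standard_mrac(total: BinaryMask,
                        params: SegmentationParams | None = None) -> AttenuationMap:
    """Vendor whole-body Dixon MR-AC emulation for this phantom: the
    entire (slightly dilated) phantom treated as soft tissue at
    0.1 cm^-1, reproducing the ~one-pixel extent overestimation."""
    params = params or SegmentationParams()
    support = total.values
    if params.standard_dilation > 0:
        support = ndimage.binary_dilation(support, structure=STRUCT_CROSS,
                                          iterations=params.standard_dilation)
    mu = np.where(support, params.mu_soft_tissue, 0.0).astype(np.float32)
    return AttenuationMap(total.grid, mu, ACMethod.STANDARD_MRAC)


def ct_to_mu(hu: np.ndarray, grid: VoxelGrid,
             scaling: BilinearScaling | None = None) -> AttenuationMap:
    """Reference CT-AC: bilinear conversion of Hounsfield units."""
    scaling = scaling or BilinearScaling()
    if not np.isfinite(hu).all():
        raise ValueError("CT volume contains non-finite values")
    return AttenuationMap(grid, scaling.mu(hu).astype(np.float32), ACMethod.CT_AC)
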