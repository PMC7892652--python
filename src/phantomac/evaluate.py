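"""Quantification-bias evaluation against the CT-AC reference.

Voxel-wise %-difference images between each MR-AC-corrected
reconstruction and the CT-AC reconstruction, summarized as mean +/- SD
in the regions used to characterize the spatial bias pattern: the whole
water compartment, single slices of the homogeneous and heterogeneous
(rod) regions, a 5-pixel water band along the phantom wall, and a
5-pixel band around all rods and the housing.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .acmaps import AttenuationMap, BinaryMask, STRUCT_CROSS, STRUCT_FULL
from .grids import VoxelGrid
from .recon import ActivityVolume


class RoiKind(str, Enum):
    WHOLE_WATER = "WHOLE_WATER"
    SLICE_HOMOGENEOUS = "SLICE_HOMOGENEOUS"
    SLICE_HETEROGENEOUS = "SLICE_HETEROGENEOUS"
    WALL_BAND = "WALL_BAND"
    ROD_BAND = "ROD_BAND"


@dataclass(frozen=True)
class RoiSpec:
    """A region request: band widths are in reconstruction-grid pixels;
    slice kinds and bands need an axial ``slice_index``."""

    kind: RoiKind
    band_width_px: int = 5
    slice_index: int | None = None

    def __post_init__(self):
        if self.band_width_px < 1:
            raise ValueError("band_width_px must be >= 1")
        needs_slice = self.kind in (RoiKind.SLICE_HOMOGENEOUS,
                                    RoiKind.SLICE_HETEROGENEOUS,
                                    RoiKind.WALL_BAND, RoiKind.ROD_BAND)
        if needs_slice and self.slice_index is None:
            raise ValueError(f"{self.kind.value} requires a slice_index")


@dataclass
class RoiReport:
    method_tag: str
    roi: RoiSpec
    mean_pct_diff: float
    sd_pct_diff: float
    n_voxels: int


def percent_difference(test: ActivityVolume, ref: ActivityVolume,
                       support: BinaryMask):
    """100 * (test - ref) / ref inside the support mask, NaN elsewhere.

    Support voxels where the reference is not strictly positive are
    excluded (NaN) and counted; returns ``(diff_volume, n_excluded)``.
    """
    if test.grid != ref.grid or test.grid != support.grid:
        raise ValueError("volumes and support must share one grid")
    diff = np.full(ref.grid.shape, np.nan)
    ok = support.values & (ref.activity > 0)
    n_excluded = int(np.count_nonzero(support.values) - np.count_nonzero(ok))
    diff[ok] = 100.0 * (test.activity[ok] - ref.activity[ok]) / ref.activity[ok]
    return diff, n_excluded


def water_support_from_ct(ct_ac: AttenuationMap,
                          mu_window=(0.090, 0.100),
                          phantom_mu_min: float = 0.05) -> BinaryMask:
    """Whole-water-compartment support by thresholding the CT-AC map.

    Voxels with mu inside the water window, restricted to the largest
    connected phantom component, then eroded by one voxel to keep
    border partial-volume voxels out of the statistics.
    """
    mu = ct_ac.mu
    in_window = (mu >= mu_window[0]) & (mu < mu_window[1])
    if not in_window.any():
        raise ValueError("no water found in the CT-AC map")
    phantom = mu > phantom_mu_min
    lab, n = ndimage.label(phantom, structure=STRUCT_FULL)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    biggest = lab == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_erosion(in_window & biggest, structure=STRUCT_CROSS)
    if not mask.any():
        raise ValueError("no water found after erosion")
    return BinaryMask(ct_ac.grid, mask)


def make_roi(roi: RoiSpec, water_support: BinaryMask,
             material: BinaryMask) -> BinaryMask:
    """Build the ROI mask for a region request.

    WALL_BAND / ROD_BAND are the water voxels of the requested slice
    within ``band_width_px`` (in-plane) pixels of the housing material
    in that slice; in a homogeneous slice the material is the shell
    only, in a rod slice it includes the rod array, so the same
    construction yields both printed band ROIs.
    """
    if water_support.grid != material.grid:
        raise ValueError("masks must share one grid")
    grid = water_support.grid
    out = np.zeros(grid.shape, dtype=bool)
    if roi.kind == RoiKind.WHOLE_WATER:
        out = water_support.values.copy()
    elif roi.kind in (RoiKind.SLICE_HOMOGENEOUS, RoiKind.SLICE_HETEROGENEOUS):
        out[:, :, roi.slice_index] = water_support.values[:, :, roi.slice_index]
    else:
        s = roi.slice_index
        mat2d = material.values[:, :, s]
        band = ndimage.binary_dilation(
            mat2d, structure=ndimage.generate_binary_structure(2, 1),
            iterations=roi.band_width_px)
        out[:, :, s] = band & water_support.values[:, :, s]
    return BinaryMask(grid, out)


def roi_stats(diff_volume: np.ndarray, roi_mask: BinaryMask,
              method_tag: str = "", roi: RoiSpec | None = None,
              sample_sd: bool = False) -> RoiReport:
    """Mean and SD of the %-difference voxels inside an ROI.

    Population SD (divide by n) by default; ``sample_sd=True`` switches
    to the n-1 convention.  NaN voxels (outside the evaluation support)
    are ignored; an effectively empty ROI is an error.
    """
    vals = diff_volume[roi_mask.values]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty ROI")
    ddof = 1 if sample_sd else 0
    sd = float(np.std(vals, ddof=ddof)) if vals.size > ddof else 0.0
    return RoiReport(
        method_tag=str(method_tag),
        roi=roi if roi is not None else RoiSpec(RoiKind.WHOLE_WATER),
        mean_pct_diff=float(np.mean(vals)),
        sd_pct_diff=sd,
        n_voxels=int(vals.size),
    )


def line_profile(volume: np.ndarray, grid: VoxelGrid, start_mm, end_mm,
                 step_mm: float = 1.0):
    """Linearly interpolated profile along a physical segment.

    Returns ``(positions_mm, values)`` with positions measured from the
    start point.  Both endpoints are always sampled and the spacing is
    adjusted to divide the segment evenly (at most ``step_mm``), so
    reversing the endpoints yields exactly the reversed profile.
    """
    start = np.asarray(start_mm, dtype=float)
    end = np.asarray(end_mm, dtype=float)
    length = float(np.linalg.norm(end - start))
    n = max(int(np.ceil(length / step_mm - 1e-9)) + 1, 2)
    t = np.linspace(0.0, length, n)
    pts = start[None, :] + (t / max(length, 1e-12))[:, None] * (end - start)[None, :]
    idx = grid.world_to_index(pts)
    vals = ndimage.map_coordinates(np.asarray(volume, dtype=float), idx.T,
                                   order=1, mode="constant", cval=0.0)
    return t, vals
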