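"""Synthetic two-point Dixon MRI and CT volumes of the voxelized phantom.

The polymer housing is MRI-visible with roughly one third of the water
signal (GRE, T1 = 194 ms, T2 = 32 ms), its main proton peak at 3.5 ppm
against water at ~4.8 ppm.  Each voxel's complex gradient-echo signal
mixes the water and polymer components according to the anti-aliased
volume fractions, so border voxels dephase (the "fat"-contrast partial
volume effect the segmentation exploits), while pure voxels show no
Dixon contrast at all.  A radial B1 bias field reproduces the signal
drop toward the compartment center, and tissue-swap-like patches inside
the housing emulate the local water/fat misassignment artifacts seen on
the scanner.

The CT counterpart is generated on the same grid in Hounsfield units,
fraction-mixed at borders, for use as the reference standard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .phantom import LabelVolume, MATERIAL
from .grids import VoxelGrid

GYROMAGNETIC_RATIO_MHZ_PER_T = 42.576


@dataclass(frozen=True)
class DixonSimParams:
    """Acquisition and artifact parameters of the Dixon simulator.

    Defaults follow the scanner protocol (TE 1.23/2.46 ms at a 2.89 T
    field, i.e. gamma*B0 = 123.2 MHz) and the published polymer
    properties (relative signal 1/3, T1 = 194 ms, T2 = 32 ms; the
    relaxation times are carried as metadata, their effect being folded
    into ``polymer_relative_signal``).  ``water_signal`` fixes the
    arbitrary-unit scale such that the segmentation thresholds (100 /
    400 / 10 a.u.) are meaningful: water ~1000 a.u., polymer ~333 a.u.

    ``psf_sigma_px`` is an isotropic (in voxel units) Gaussian
    acquisition point-spread applied to the complex channels.  Its
    default is calibrated so that, even without noise, the support of
    the opposed-phase image above the low segmentation threshold
    overshoots the true surface by about one voxel — the overestimation
    the segmentation's 1-voxel erosion exists to compensate (on a real
    scanner the noise floor and edge artifacts contribute to that
    overshoot; a blur-only model needs the larger sigma).
    """

    te1_ms: float = 1.23
    te2_ms: float = 2.46
    field_strength_t: float = 2.894
    water_shift_ppm: float = 4.8
    polymer_shift_ppm: float = 3.5
    water_signal: float = 1000.0
    polymer_relative_signal: float = 1.0 / 3.0
    polymer_t1_ms: float = 194.0
    polymer_t2_ms: float = 32.0
    bias_min: float = 0.7
    psf_sigma_px: float = 1.6
    swap_patch_count: int = 3
    swap_patch_radius_mm: float = 12.0
    noise_sigma: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if not self.te2_ms > self.te1_ms > 0:
            raise ValueError("need te2 > te1 > 0")
        if not 0 < self.polymer_relative_signal <= 1:
            raise ValueError("polymer_relative_signal must be in (0, 1]")
        if not 0 < self.bias_min <= 1:
            raise ValueError("bias_min must be in (0, 1]")
        if self.noise_sigma < 0 or self.psf_sigma_px < 0:
            raise ValueError("noise and PSF sigmas must be >= 0")

    def larmor_mhz(self) -> float:
        return GYROMAGNETIC_RATIO_MHZ_PER_T * self.field_strength_t

    def phase_rad(self, shift_ppm: float, te_ms: float) -> float:
        """Accrued phase 2*pi*f*TE of a component at chemical shift ``shift_ppm``."""
        f_hz = shift_ppm * 1e-6 * self.larmor_mhz() * 1e6
        return 2.0 * np.pi * f_hz * te_ms * 1e-3


@dataclass
class DixonStudy:
    """The four magnitude volumes of a two-point Dixon acquisition."""

    grid: VoxelGrid
    in_phase: np.ndarray
    opposed_phase: np.ndarray
    fat: np.ndarray
    water: np.ndarray

    def __post_init__(self):
        for name in ("in_phase", "opposed_phase", "fat", "water"):
            v = getattr(self, name)
            if v.shape != self.grid.shape:
                raise ValueError(f"{name} shape does not match grid")
            if np.any(v < 0):
                raise ValueError(f"{name} must be nonnegative (magnitude image)")


@dataclass
class CTVolume:
    grid: VoxelGrid
    hu: np.ndarray

    def __post_init__(self):
        if self.hu.shape != self.grid.shape:
            raise ValueError("hu shape does not match grid")


def radial_bias_field(label: LabelVolume, bias_min: float) -> np.ndarray:
    """Multiplicative B1 field: 1 at the compartment edge, ``bias_min``
    at the center, quadratic in the transaxial radius, clamped at 1."""
    grid = label.grid
    xs = grid.axis_coords(0)[:, None]
    ys = grid.axis_coords(1)[None, :]
    r2 = xs * xs + ys * ys
    wet = label.frac_water > 0
    if wet.any():
        r2_max = float(r2[wet.any(axis=2)].max())
    else:
        r2_max = float(r2.max())
    r2_max = max(r2_max, 1e-9)
    b2d = 1.0 - (1.0 - bias_min) * (1.0 - r2 / r2_max)
    b2d = np.clip(b2d, bias_min, 1.0)
    return np.repeat(b2d[:, :, None], grid.shape[2], axis=2)


def simulate_dixon(label: LabelVolume, params: DixonSimParams) -> DixonStudy:
    """Simulate in-phase / opposed-phase / fat / water magnitude images.

    The complex signal at echo time TE is

        S(TE) = B(x) * [w * W * exp(i 2 pi f_w TE) + p * P * exp(i 2 pi f_p TE)]

    with w, p the anti-aliased water/polymer fractions, W the water
    amplitude, P its polymer counterpart, and f the chemical-shift
    frequencies.  The complex channels are blurred by the acquisition
    PSF, complex Gaussian noise is added (magnitudes become Rician), and
    the two-point magnitude recombination water = (IP + OP)/2,
    fat = |IP - OP|/2 is applied.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    w = label.frac_water.astype(np.float64)
    p = label.frac_material.astype(np.float64)
    bias = radial_bias_field(label, params.bias_min)

    W = params.water_signal
    P = params.polymer_relative_signal * W
    mags = []
    for te in (params.te1_ms, params.te2_ms):
        phi_w = params.phase_rad(params.water_shift_ppm, te)
        phi_p = params.phase_rad(params.polymer_shift_ppm, te)
        sig = bias * (w * W * np.exp(1j * phi_w) + p * P * np.exp(1j * phi_p))
        re, im = sig.real.copy(), sig.imag.copy()
        if params.psf_sigma_px > 0:
            re = gaussian_filter(re, params.psf_sigma_px)
            im = gaussian_filter(im, params.psf_sigma_px)
        if params.noise_sigma > 0:
            re = re + rng.normal(0.0, params.noise_sigma, size=re.shape)
            im = im + rng.normal(0.0, params.noise_sigma, size=im.shape)
        mags.append(np.hypot(re, im))
    opposed_phase, in_phase = mags  # TE1 -> "opposed", TE2 -> "in-phase"

    water_img = (in_phase + opposed_phase) / 2.0
    fat_img = np.abs(in_phase - opposed_phase) / 2.0

    # tissue-swap-like artifacts: exchange fat/water inside spherical
    # patches restricted to the housing material
    n_patch = int(params.swap_patch_count)
    mat_idx = np.argwhere(label.labels == MATERIAL)
    if n_patch > 0 and len(mat_idx) > 0:
        grid = label.grid
        picks = rng.choice(len(mat_idx), size=n_patch, replace=False)
        xs = grid.axis_coords(0)[:, None, None]
        ys = grid.axis_coords(1)[None, :, None]
        zs = grid.axis_coords(2)[None, None, :]
        for pick in picks:
            i, j, k = mat_idx[pick]
            cx = grid.axis_coords(0)[i]
            cy = grid.axis_coords(1)[j]
            cz = grid.axis_coords(2)[k]
            sphere = ((xs - cx) ** 2 + (ys - cy) ** 2 + (zs - cz) ** 2
                      <= params.swap_patch_radius_mm ** 2)
            patch = sphere & (label.labels == MATERIAL)
            fat_img[patch], water_img[patch] = (water_img[patch].copy(),
                                                fat_img[patch].copy())

    return DixonStudy(label.grid, in_phase, opposed_phase, fat_img, water_img)


def simulate_ct(label: LabelVolume, hu_water: float = 0.0,
                hu_material: float | None = None,
                noise_sigma: float = 0.0, seed: int = 0) -> CTVolume:
    """Synthetic co-registered CT in Hounsfield units.

    Background is air (-1000 HU), water 0 HU; the housing material HU
    defaults to the value whose bilinear conversion yields the printed
    polymer attenuation of 0.1037 cm^-1 at 511 keV (~110 HU at 120 kVp,
    consistent with an acrylic-like polymer).  Border voxels are mixed
    by volume fraction; output is clamped at -1000 HU.
    """
    if hu_material is None:
        from .acmaps import BilinearScaling, MU_MATERIAL
        hu_material = BilinearScaling().hu_for_mu(MU_MATERIAL)
    w = label.frac_water.astype(np.float64)
    p = label.frac_material.astype(np.float64)
    bg = np.clip(1.0 - w - p, 0.0, 1.0)
    hu = -1000.0 * bg + hu_water * w + hu_material * p
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, noise_sigma, size=hu.shape)
    hu = np.maximum(hu, -1000.0)
    return CTVolume(label.grid, hu.astype(np.float32))
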