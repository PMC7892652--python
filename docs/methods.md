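# Methods

## The experiment being modelled

A water-fillable cylindrical phantom printed from an MRI-visible polymer
is filled with an aqueous [18F]FDG solution at 10 kBq/ml and scanned on
a PET/MRI system; a CT of the same phantom provides the reference
attenuation map.  Four attenuation-correction (AC) maps are compared by
reconstructing the same emission data with each and measuring the
voxel-wise % difference of the resulting PET images against the CT-AC
reconstruction: a phantom-specific MR-AC segmented from the Dixon
images, the vendor-style standard MR-AC, a NoWall map that ignores the
housing (the situation with a conventional, MRI-invisible phantom), and
CT-AC itself.  `phantomac` reproduces the full chain on synthetic data
so the comparison can be run, tested and extended without a scanner.

## Phantom geometry

Printed dimensions: outer diameter 25.2 cm, shell 6 mm, top/bottom lids
10/5 mm, inner compartment 24 cm diameter × 18.5 cm, rods of 5 cm length
with diameters {5, 10, 13, 17, 22, 28} mm standing on the bottom lid.
These five constraints over-determine the cylinder: an 18.5 cm inner
length plus 1.5 cm of lids gives a 20.0 cm outer length, which is what
`PhantomSpec` uses (the quantities that drive the attenuation physics —
inner compartment, shell, lids — are kept exact, and the geometric
identity inner = outer − lids is enforced as a class invariant).

The rod-array layout is not fully specified by the source geometry
drawing; the default is a documented sector layout (one diameter per
60° sector, square lattice at twice-the-diameter pitch, ≥5 mm wall
clearance, 78 rods in total) and any per-rod (center, diameter) list can
be supplied instead.

Voxelization samples `subsampling³` points per voxel (default 3³) and
stores both anti-aliased volume fractions and majority-vote labels;
ties go to material over water over background.  On a 1 mm grid the
label volumes match the closed-form cylinder volumes to well under 1 %,
and the fraction fields (used by the signal simulators and as ground
truth μ) are a further order of magnitude tighter.

## Dixon signal model

Each voxel's complex gradient-echo signal at echo time TE is

    S(TE) = B(x) · [ w·W·e^{i·2π·f_w·TE} + p·P·e^{i·2π·f_p·TE} ]

with `w, p` the water/polymer volume fractions, `W = 1000 a.u.` the
water amplitude, `P = W/3` (the polymer's published relative GRE
signal; its T1 = 194 ms and T2 = 32 ms are carried as metadata, their
net effect being folded into this amplitude ratio), and `f = δ·γB0` the
chemical-shift frequencies (water 4.8 ppm, polymer main peak 3.5 ppm,
γB0 = 123.2 MHz, i.e. a 2.89 T system; Δf ≈ 160 Hz).  The two echoes use
the whole-body protocol's TE = 1.23/2.46 ms.  Magnitude recombination
is plain two-point Dixon: water = (IP + OP)/2, fat = |IP − OP|/2 — the
vendor's actual algorithm is proprietary, but for a non-lipid material
only the partial-volume dephasing at borders produces "fat" contrast
either way, which is precisely the effect the segmentation exploits.
At the protocol TEs a 50/50 border voxel dephases by 1.24 rad at the
first echo; at the material-matched TEs of 3.39/6.78 ms it dephases by
≈π and the first echo collapses to |W − P|/2 (both regimes are covered
by tests).

Multiplicative B1 field: B = 1 − (1 − b_min)·(1 − (r/R)²) with r the
transaxial radius and R the compartment radius; default b_min = 0.7
(the magnitude of the centre signal drop is not quantified by the
source; 30 % is typical for a 25 cm water cylinder at 3 T).  Complex
Gaussian noise (default σ = 25 a.u. = SNR 40 in water) makes the
magnitudes Rician.  Tissue-swap emulation exchanges the fat/water
channel values inside spherical patches confined to the housing
material; it deliberately leaves the raw echoes untouched.

**Acquisition PSF and its calibration.**  An isotropic-in-voxels
Gaussian PSF (`psf_sigma_px`, default 1.6) is applied to the complex
channels.  Its default is set by a segmentation-level criterion: the
support of the opposed-phase image above the low threshold (100 a.u. =
30 % of the polymer level) must overshoot the true surface by about one
voxel, because the pipeline's isotropic 1-voxel erosion exists to take
exactly that overshoot back.  On real scanner data the overshoot is
produced jointly by the PSF, the noise floor and edge artifacts; a
blur-only simulator needs σ ≈ 1.6 px to reproduce it in the noiseless
evaluation condition.  Two printed behaviours then emerge without
further tuning: the housing extent is overestimated into the water by a
fraction of a pixel up to about one pixel (the partial-volume/fat-
subtraction ring), and neighbouring rods can merge across the coarse
slice direction.  The trade-off of this calibration is resolution: at
σ = 1.6 px the 5 mm rods (1.9 Dixon pixels) are largely absorbed into
the water compartment, which in turn makes the NoWall bias around the
rod array milder than on the scanner (see Limitations).

The default acquisition grid is the whole-body Dixon-AC protocol in its
coronal orientation: 2.6 × 2.6 mm² pixels, 3.1 mm slices stacked
*perpendicular to the phantom axis* (192 × 120 in-plane, 128 slices), so
the coarse direction is transaxial, as on the scanner.

## CT and the bilinear scaling

The synthetic CT mixes −1000 HU (air), 0 HU (water) and the housing HU
by volume fraction.  HU → μ(511 keV) uses the standard 120 kVp bilinear
scaling: μ = 9.6·10⁻⁵·(HU + 1000) cm⁻¹ up to 47 HU, slope 5.1·10⁻⁵
above, continuous at the break; 0 HU maps to 0.096 cm⁻¹.  The housing
HU default (≈110 HU) is defined by inverting this scaling at the
printed polymer attenuation of 0.1037 cm⁻¹ — a density consistent with
an acrylic-like polymer.

## Segmentation and the four maps

Total phantom: opposed-phase > 100 a.u. → closing → largest 26-connected
component → 1-voxel 6-connected erosion.  Water: fat filtered with a
0.5 px Gaussian and floored at 10 a.u., subtracted four times from the
opposed-phase image, thresholded at 400 a.u., closed.  Material = total
∖ water.  Closing uses a radius-1 cross by default: its printed purpose
is absorbing individual sub-threshold pixels, and any radius large
enough to close rod-scale gaps would delete the rod array from the
material compartment (the closing is implemented pad-extended so it is
a true no-op on solid objects at the array border).  All structuring
elements and radii are parameters.

Maps: phantom MR-AC assigns 0.096/0.1037 cm⁻¹ to water/material;
NoWall-AC zeroes the material; standard MR-AC emulation dilates the
total support by one pixel and assigns 0.1 cm⁻¹ throughout (the
scanner's behaviour for this phantom: soft tissue everywhere, extent
overestimated by ~2 mm); CT-AC applies the bilinear scaling.  Masks are
built on the Dixon grid and moved to the reconstruction grid by
nearest-neighbour resampling before μ assignment (binary masks stay
binary); the continuous CT-AC map moves trilinearly.

## PET forward model and reconstruction

Transport is slice-wise 2D parallel-beam: the AC bias under study is a
line-integral effect, and for coincidence detection the attenuation
factor exp(−∫μ dl) of a line of response is independent of the emission
point, so y(θ,s,z) = [ray transform of activity]·[survival factor].
Scatter, randoms, normalization and time-of-flight are not modelled, so
ordinary-Poisson OSEM reduces to plain OSEM with the survival factors
of the chosen AC map inside the system model.  The projector is
rotate-and-sum with linear interpolation and its matching adjoint;
96 azimuthal angles over [0, π) are the default (the scanner's sinogram
has 252; 48 visibly under-samples the near-tangent rays that carry the
wall-band bias, 96 is the desk-scale compromise).

Reconstruction: OSEM, 3 iterations × 24 subsets, uniform positive
initialization, subset sensitivity normalization, 5-mm FWHM Gaussian
post-filter — the scanner protocol.  The reconstruction grid keeps the
scanner's 2.09 mm in-plane pixel so that pixel-denominated quantities
(the 5-pixel ROI bands, the one-pixel dilation) retain their physical
width, with the field of view cropped to 192 × 192 pixels around the
phantom and 40 axial slices of 5 mm covering it; this stands in for the
scanner's 344 × 344 × 127 matrix at desk scale.  Poisson count noise is
available (seeded) but off in the evaluation condition, so that the
reconstructions differ only through their AC maps.

## Evaluation

The water-compartment support is obtained from the CT-AC map (μ in
[0.090, 0.100) cm⁻¹, largest phantom component, 1-voxel erosion against
border partial volume).  %-difference images are 100·(test − ref)/ref
on that support; ROI statistics use the population SD (divide by n; a
flag switches to n−1).  ROIs: whole water compartment; a single slice
through the axial middle of the rod-free region ("homogeneous") and of
the rod region ("heterogeneous"); the water voxels of those slices
within 5 in-plane reconstruction pixels (10.5 mm) of the housing
material — along the wall in the homogeneous slice, around rods plus
housing in the heterogeneous slice.  Band ROIs are defined against the
ground-truth material labels on the reconstruction grid.  Line profiles
(linear interpolation along an arbitrary mm segment) are provided for
inspection of the AC maps and PET images across the wall and rods.

## What the synthetic data does and does not emulate

Emulated: partial-volume mixing at every compartment border (the source
of the Dixon "fat" contrast), the centre-ward B1 signal drop, Rician
magnitude statistics, tissue-swap-like artifacts confined to the
housing, the coronal anisotropic acquisition grid, CT border mixing,
attenuated projection and subset-EM reconstruction with the protocol's
settings.

Not emulated: 3D oblique lines of response (transport is slice-wise
2D), scatter and randoms and their AC-map-dependent corrections, Gibbs
ringing and B0-related distortions, the vendor's proprietary water/fat
solver and μ-map post-processing, detector normalization and
resolution modelling.  Consequences observed in the end-to-end run:
whole-compartment biases and their spatial ordering reproduce the
scanner experiment closely (phantom MR-AC ≈ 0, standard ≈ +13 vs
printed +9.4, NoWall ≈ −21 vs −24.1, wall band −32 vs −34.3), while the
rod-band NoWall bias is shallower (≈ −35 vs −45.5) because the 5 mm rod
sector falls below the simulator's effective resolution and survives in
the water mask, and because 2D transport misses oblique paths through
the rod forest.  Passing tests therefore demonstrate the pipeline's
correctness and the bias mechanism, not scanner-exact rod-scale
quantitation.

## Numerical choices

- Voxel boxes are half-open; subsample points are symmetric within the
  voxel; label ties resolve toward the attenuating class.
- The projector requires a square in-plane grid with isotropic in-plane
  spacing; line integrals are in (quantity)·cm.
- OSEM guards divisions with ε = 10⁻¹²; voxels with zero subset
  sensitivity stay zero; nonnegativity is structural.
- Subset k of n takes angles {k, k+n, …} — with 96 angles and 24
  subsets, the 4 angles of a subset are 45° apart.
- `%`-difference voxels with a nonpositive reference are excluded and
  tallied rather than propagated.
- All randomness flows from `numpy.random.default_rng(seed)`; an
  experiment config carries one master seed from which stage seeds are
  derived, and identical configs produce byte-identical report CSVs.

## Problem sizes

The default end-to-end experiment (2.9 M-voxel Dixon grid, 1.5 M-voxel
reconstruction grid, 96 angles, four reconstructions) runs in about
four minutes on a single CPU; the test suite's miniature configuration
(coarse 5–6 mm grids, 24 angles, 2 × 12 OSEM) runs in seconds and is
used wherever the full scale is not the point.
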