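# phantomac

Attenuation correction (AC) for PET/MRI phantom studies, built around a
water-fillable cylindrical phantom 3D-printed from an MRI-visible
polymer.  Conventional phantom housings are invisible to MRI, so the
standard Dixon-based MR-AC of a PET/MRI system cannot account for their
photon attenuation and the reconstructed activity is biased low.  An
MRI-visible housing changes that: the polymer produces roughly one third
of the water signal in gradient-echo images, so simple thresholding of
the Dixon volumes can separate housing from water and assign each its
511 keV linear attenuation coefficient.

`phantomac` implements that pipeline end to end, for synthetic data
generated from the phantom's geometry and physics (no scanner needed)
or for user-supplied co-registered Dixon/CT NIfTI volumes:

1. **Phantom model** — parametric geometry (25.2 cm outer diameter, 6 mm
   polymer shell, 10/5 mm lids, 24 cm × 18.5 cm water compartment, a
   Jaszczak-style rod array of diameters 5–28 mm) voxelized with
   anti-aliased partial-volume fractions.
2. **Dixon + CT simulator** — two-point complex gradient-echo signal
   model (TE 1.23/2.46 ms, water 4.8 ppm vs polymer 3.5 ppm at
   γ·B0 = 123.2 MHz), radial B1 bias field, acquisition PSF, Rician
   noise, tissue-swap-like artifacts; co-registered CT in Hounsfield
   units.
3. **AC maps** — the threshold/morphology segmentation (total phantom:
   opposed-phase > 100 a.u., closing, largest component, 1-voxel
   erosion; water: opposed-phase − 4 × filtered fat > 400 a.u.) and four
   maps: phantom-specific MR-AC (water 0.096 cm⁻¹, housing
   0.1037 cm⁻¹), NoWall-AC (housing ignored), standard whole-body MR-AC
   emulation (everything 0.1 cm⁻¹, one-pixel dilation), and the bilinear
   CT-AC reference.
4. **PET simulator** — slice-wise parallel-beam attenuated forward
   projection, `y = (∫a dl)·exp(−∫μ dl)`, and op-OSEM reconstruction
   (3 iterations × 24 subsets, 5-mm FWHM Gaussian post-filter).
5. **Evaluation** — voxel %-difference images vs the CT-AC
   reconstruction and mean ± SD statistics in the whole water
   compartment, single slices, and 5-pixel bands along the wall and
   around the rods.

## Worked example

```python
from phantomac.pipeline import (default_experiment_config, run_experiment,
                                headline_biases)

cfg = default_experiment_config(seed=1, noiseless=True)
result = run_experiment(cfg)          # ~4 minutes on one CPU
for key, v in headline_biases(result).items():
    print(f"{key:20s} {v['value']:+7.2f} %   ({v['n']} voxels)")
```

prints

```
phantom_whole          +0.17 %   (337326 voxels)
standard_whole        +13.01 %   (337326 voxels)
nowall_whole          -20.56 %   (337326 voxels)
nowall_wall_band      -31.98 %   (1228 voxels)
standard_wall_band    +11.53 %   (1228 voxels)
nowall_rod_band       -34.76 %   (4410 voxels)
nowall_het_slice      -31.04 %   (7904 voxels)
```

Reading the numbers: with the phantom-specific MR-AC the reconstruction
agrees with the CT-AC reference to well under 1 % over the whole water
compartment — an MRI-visible housing makes a CT attenuation template
unnecessary.  Treating the whole phantom as soft tissue (the vendor-style
standard MR-AC) overestimates activity by ~13 %, and ignoring the
housing entirely (NoWall, the situation with a conventional phantom)
underestimates it by ~20 % overall, worsening to ~−32 % in the 5-pixel
water band along the wall and ~−35 % around the rod array, where lines
of response cross the most unaccounted polymer.

`result.table` holds the full method × ROI table (mean, SD, voxel
counts) as a `pandas.DataFrame`; `run_experiment(cfg, output_dir=...)`
additionally writes all volumes as NIfTI, the sinogram with a JSON
geometry sidecar, the ROI table as CSV and the exact config + hash.

The same stages are scriptable from the shell:

```bash
phantomac run-all --seed 1 --out out/            # full chain
phantomac simulate --seed 1 --out study/         # Dixon + CT volumes only
phantomac build-acmaps --dixon-op study/dixon_opposed_phase.nii.gz \
    --dixon-fat study/dixon_fat.nii.gz --method phantom --out mrac.nii.gz
```

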