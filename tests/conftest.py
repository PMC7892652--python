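"""Shared fixtures: one noiseless study-scale simulation reused by the
segmentation tests, plus a miniature experiment config for fast
end-to-end checks."""

import dataclasses

import numpy as np
import pytest

from phantomac import (
    BinaryMask,
    DixonSimParams,
    SegmentationParams,
    VoxelGrid,
    default_phantom_spec,
    material_mask,
    rasterize,
    simulate_dixon,
    total_phantom_mask,
    water_mask,
)
from phantomac.pipeline import ExperimentConfig, default_experiment_config
from phantomac.recon import ReconParams


@pytest.fixture(scope="session")
def spec():
    return default_phantom_spec()


@pytest.fixture(scope="session")
def study_label(spec):
    """Default phantom rasterized on the acquisition (Dixon) grid."""
    cfg = default_experiment_config(seed=0)
    return rasterize(spec, cfg.dixon_grid, cfg.subsampling)


@pytest.fixture(scope="session")
def noiseless_study(study_label):
    cfg = default_experiment_config(seed=0, noiseless=True)
    return simulate_dixon(study_label, cfg.dixon)


@pytest.fixture(scope="session")
def noisy_study(study_label):
    cfg = default_experiment_config(seed=0, noiseless=False)
    return simulate_dixon(study_label, cfg.dixon)


@pytest.fixture(scope="session")
def segmentation(noiseless_study):
    """(total, water, material) masks from the noiseless default study."""
    grid = noiseless_study.grid
    params = SegmentationParams()
    total = total_phantom_mask(noiseless_study.opposed_phase, grid, params)
    water = water_mask(noiseless_study.opposed_phase, noiseless_study.fat,
                       grid, params)
    water = BinaryMask(grid, water.values & total.values)
    return total, water, material_mask(total, water)


def mini_config(seed: int = 0) -> ExperimentConfig:
    """Coarse, fast experiment configuration (full phantom, small grids)."""
    cfg = default_experiment_config(seed=seed, noiseless=True)
    return dataclasses.replace(
        cfg,
        dixon_grid=VoxelGrid.centered((64, 52, 42), (5.2, 6.2, 5.2), z_min=-5.0),
        recon_grid=VoxelGrid.centered((64, 64, 13), (6.27, 6.27, 16.0), z_min=-4.0),
        n_angles=24,
        recon=ReconParams(iterations=2, subsets=12, postfilter_fwhm_mm=5.0),
        subsampling=2,
    )


@pytest.fixture()
def tiny_label():
    """Hand-built label volume with a flat water/material interface and
    exact fractions, for unit-level Dixon physics checks."""
    from phantomac.phantom import LabelVolume

    grid = VoxelGrid((8, 8, 4), (2.0, 2.0, 2.0))
    fw = np.zeros(grid.shape, dtype=np.float32)
    fm = np.zeros(grid.shape, dtype=np.float32)
    fw[:3] = 1.0          # pure water slab
    fm[5:] = 1.0          # pure material slab
    fw[3], fm[3] = 0.5, 0.5   # 50/50 partial-volume plane
    fm[4] = 1.0
    labels = np.zeros(grid.shape, dtype=np.uint8)
    labels[:4] = 2
    labels[4:] = 1
    return LabelVolume(grid, labels, fm, fw)
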