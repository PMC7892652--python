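"""Projector, attenuation factors and OSEM against closed-form oracles."""

import numpy as np
import pytest

from phantomac import (
    ACMethod,
    ActivityVolume,
    AttenuationMap,
    ParallelProjector,
    ReconParams,
    Sinogram,
    VoxelGrid,
    attenuation_factors,
    forward_project,
    osem_reconstruct,
    poisson_loglik,
)


def disk_volume(grid, radius_mm, value, supersample=4):
    """Anti-aliased uniform disk, replicated over slices."""
    n = supersample
    off = (np.arange(n) + 0.5) / n - 0.5
    acc = np.zeros(grid.shape[:2])
    for ox in off:
        for oy in off:
            xs = grid.axis_coords(0) + ox * grid.spacing[0]
            ys = grid.axis_coords(1) + oy * grid.spacing[1]
            acc += (xs[:, None] ** 2 + ys[None, :] ** 2) <= radius_mm ** 2
    frac = acc / n ** 2
    return np.repeat((value * frac)[:, :, None], grid.shape[2], axis=2)


@pytest.fixture(scope="module")
def grid64():
    return VoxelGrid.centered((64, 64, 2), (2.0, 2.0, 2.0))


class TestProjector:
    def test_disk_projection_matches_chord_lengths(self, grid64):
        """The ray transform of a uniform disk is value * chord length
        2*sqrt(R^2 - s^2)."""
        proj = ParallelProjector(grid64, n_angles=8)
        act = disk_volume(grid64, 40.0, 3.0)
        sino = proj.forward(act)
        s_mm = (np.arange(64) - 31.5) * 2.0
        chord_cm = 2.0 * np.sqrt(np.clip(40.0 ** 2 - s_mm ** 2, 0, None)) / 10.0
        expected = 3.0 * chord_cm
        for a in range(8):
            interior = np.abs(s_mm) < 32.0     # away from the tangent rays
            assert sino[a, interior, 0] == pytest.approx(expected[interior],
                                                         rel=0.02)

    def test_central_ray_attenuation_factor_of_uniform_cylinder(self, grid64):
        mu = AttenuationMap(grid64, disk_volume(grid64, 40.0, 0.1),
                            ACMethod.GROUND_TRUTH)
        proj = ParallelProjector(grid64, n_angles=6)
        att = attenuation_factors(mu, proj).values
        central = np.argmin(np.abs((np.arange(64) - 31.5) * 2.0))
        expected = np.exp(-0.1 * 8.0)      # exp(-mu * diameter), diameter 8 cm
        assert att[:, central, 0] == pytest.approx(expected, rel=0.01)

    def test_zero_mu_gives_unit_factors(self, grid64):
        mu = AttenuationMap(grid64, np.zeros(grid64.shape), ACMethod.GROUND_TRUTH)
        att = attenuation_factors(mu, ParallelProjector(grid64, 4)).values
        assert np.all(att == 1.0)

    def test_factors_decrease_as_mu_scales_up(self, grid64):
        proj = ParallelProjector(grid64, 4)
        base = disk_volume(grid64, 40.0, 0.05)
        a1 = attenuation_factors(
            AttenuationMap(grid64, base, ACMethod.GROUND_TRUTH), proj).values
        a2 = attenuation_factors(
            AttenuationMap(grid64, 2 * base, ACMethod.GROUND_TRUTH), proj).values
        assert (a2 <= a1 + 1e-12).all()

    def test_zero_activity_projects_to_zero(self, grid64):
        proj = ParallelProjector(grid64, 4)
        act = ActivityVolume(grid64, np.zeros(grid64.shape))
        mu = AttenuationMap(grid64, disk_volume(grid64, 40.0, 0.1),
                            ACMethod.GROUND_TRUTH)
        assert np.all(forward_project(act, mu, proj).values == 0.0)

    def test_poisson_mode_is_seeded(self, grid64):
        proj = ParallelProjector(grid64, 4)
        act = ActivityVolume(grid64, disk_volume(grid64, 40.0, 10.0))
        mu = AttenuationMap(grid64, disk_volume(grid64, 40.0, 0.096),
                            ACMethod.GROUND_TRUTH)
        a = forward_project(act, mu, proj, poisson=True, seed=7)
        b = forward_project(act, mu, proj, poisson=True, seed=7)
        c = forward_project(act, mu, proj, poisson=True, seed=8)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)


@pytest.fixture(scope="module")
def water_cylinder(grid64):
    act = ActivityVolume(grid64, disk_volume(grid64, 44.0, 10.0))
    mu = AttenuationMap(grid64, disk_volume(grid64, 44.0, 0.096),
                        ACMethod.GROUND_TRUTH)
    proj = ParallelProjector(grid64, n_angles=48)
    sino = forward_project(act, mu, proj)
    return act, mu, proj, sino


class TestOsem:

    def test_matched_ac_recovers_truth_within_2pct(self, water_cylinder):
        act, mu, proj, sino = water_cylinder
        rec = osem_reconstruct(sino, mu, ReconParams(iterations=3, subsets=24),
                               proj)
        xs = mu.grid.axis_coords(0)
        interior = (xs[:, None] ** 2 + xs[None, :] ** 2) < 30.0 ** 2
        mean = rec.activity[:, :, 0][interior].mean()
        assert mean == pytest.approx(10.0, rel=0.02)

    def test_missing_attenuation_correction_underestimates(self, water_cylinder):
        act, mu, proj, sino = water_cylinder
        no_ac = AttenuationMap(mu.grid, np.zeros(mu.grid.shape), ACMethod.NOWALL_MRAC)
        rec = osem_reconstruct(sino, no_ac, ReconParams(iterations=3, subsets=24),
                               proj)
        xs = mu.grid.axis_coords(0)
        interior = (xs[:, None] ** 2 + xs[None, :] ** 2) < 30.0 ** 2
        assert rec.activity[:, :, 0][interior].mean() < 9.0

    def test_reconstruction_reproduces_its_own_data(self, water_cylinder):
        """On noiseless, consistent data the converged OSEM estimate is
        a fixed point: re-projecting it reproduces the sinogram."""
        act, mu, proj, sino = water_cylinder
        rec = osem_reconstruct(sino, mu, ReconParams(iterations=3, subsets=24,
                                                     postfilter_fwhm_mm=0.0), proj)
        resid = proj.forward(rec.activity) * attenuation_factors(mu, proj).values
        rel = np.abs(resid - sino.values)[sino.values > 1e-6] / sino.values[sino.values > 1e-6]
        assert np.median(rel) < 0.02

    def test_loglikelihood_nondecreasing_over_full_iterations(self, water_cylinder):
        act, mu, proj, sino = water_cylinder
        lls = []
        for it in (1, 2, 4):
            rec = osem_reconstruct(sino, mu,
                                   ReconParams(iterations=it, subsets=8,
                                               postfilter_fwhm_mm=0.0), proj)
            expected = Sinogram(proj.geometry,
                                proj.forward(rec.activity)
                                * attenuation_factors(mu, proj).values)
            lls.append(poisson_loglik(sino, expected))
        assert lls[1] >= lls[0] - 1e-6 * abs(lls[0])
        assert lls[2] >= lls[1] - 1e-6 * abs(lls[1])

    def test_invalid_subset_partition_is_an_error(self, water_cylinder):
        act, mu, proj, sino = water_cylinder
        with pytest.raises(ValueError, match="invalid subset partition"):
            osem_reconstruct(sino, mu, ReconParams(iterations=1, subsets=7), proj)

    def test_nonnegativity_preserved(self, water_cylinder):
        act, mu, proj, sino = water_cylinder
        rec = osem_reconstruct(sino, mu, ReconParams(iterations=2, subsets=8), proj)
        assert rec.activity.min() >= 0.0
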