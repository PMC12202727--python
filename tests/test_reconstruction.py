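"""Reconstruction: Cartesian FFT, zero-fill enhancement, gridding,
echo combination, compressed sensing, MIP."""

import numpy as np
import pytest

from voidlapse.acquisition import CartesianSchedule, KSpaceData, RadialSchedule, acquire
from voidlapse.phantom import ImageGrid, Particle, Scene, bandlimited_render
from voidlapse.quantify import measure_spot
from voidlapse.reconstruction import (
    CSConfig,
    cartesian_recon,
    combine_echoes,
    cs_recon,
    density_compensation,
    grid_recon,
    mip_render,
    sos_combine,
    zero_fill_enhance,
)


class TestCartesian:
    def test_uniform_disk_interior(self, small_cartesian, grid2d):
        img = cartesian_recon(acquire(Scene(), small_cartesian, seed=0))
        xs = grid2d.coords()
        interior = xs[0] ** 2 + xs[1] ** 2 < (0.7 * Scene().cylinder_radius) ** 2
        assert np.abs(img[interior] - 1.0).max() < 0.02  # Gibbs excluded near edge

    def test_impulse_psf_peaks_at_object(self, small_cartesian, grid2d):
        # deep narrow void: minimum of the image at the particle's voxel
        p = Particle(0, np.array([1.8, -0.9]), void_amplitude=1.0, void_sigma=0.25)
        img = cartesian_recon(acquire(Scene(particles=[p]), small_cartesian, seed=0))
        xs = grid2d.coords()
        inside = xs[0] ** 2 + xs[1] ** 2 < (0.8 * Scene().cylinder_radius) ** 2
        masked = np.where(inside, img, np.inf)
        assert np.unravel_index(np.argmin(masked), img.shape) == grid2d.index_of(p.position0)

    def test_linearity(self, small_cartesian):
        sc = Scene(particles=[Particle(0, np.array([1.0, 1.0]))])
        kd = acquire(sc, small_cartesian, seed=0)
        scaled = KSpaceData(
            samples=3.0 * kd.samples,
            trajectory=kd.trajectory,
            timestamps=kd.timestamps,
            noise_sigma=0.0,
            schedule=kd.schedule,
            meta=kd.meta,
        )
        np.testing.assert_allclose(cartesian_recon(scaled), 3.0 * cartesian_recon(kd), rtol=1e-12)

    def test_missing_lines_rejected(self, small_cartesian):
        sc = Scene()
        kd = acquire(sc, small_cartesian, seed=0)
        kd.samples = kd.samples[:, :-1, :]
        with pytest.raises(ValueError):
            cartesian_recon(kd)


class TestZeroFill:
    def test_factor_one_is_identity(self, small_cartesian, static_scene_2d):
        kd = acquire(static_scene_2d, small_cartesian, seed=0)
        np.testing.assert_allclose(zero_fill_enhance(kd, 1), cartesian_recon(kd), atol=1e-12)

    def test_never_increases_minimum(self, small_cartesian, static_scene_2d):
        kd = acquire(static_scene_2d, small_cartesian, seed=0)
        enh = zero_fill_enhance(kd, 4)
        nat = cartesian_recon(kd)
        assert enh.min() <= nat.min() + 1e-12

    def test_enhancement_deepens_void(self, small_cartesian, grid2d):
        # particle deliberately between voxel centres (multiples of the
        # 0.2 mm voxel land midway on the half-offset grid)
        p = Particle(0, np.array([1.6, 0.8]), void_amplitude=0.32, void_sigma=0.12)
        kd = acquire(Scene(particles=[p]), small_cartesian, seed=0)
        sl_nat = measure_spot(cartesian_recon(kd), grid2d.index_of(p.position0)).sl
        sl_enh = measure_spot(zero_fill_enhance(kd, 4), grid2d.index_of(p.position0)).sl
        assert sl_enh >= sl_nat

    def test_non_integer_factor(self, small_cartesian, static_scene_2d):
        kd = acquire(static_scene_2d, small_cartesian, seed=0)
        with pytest.raises(ValueError):
            zero_fill_enhance(kd, 2.5)


class TestDensityCompensation:
    def test_2d_ramp_filter(self):
        radii = np.linspace(0, 1.0, 33)
        w = density_compensation(radii, 2, 100)
        prop = w[2:] / radii[2:]
        np.testing.assert_allclose(prop, prop[-1], rtol=1e-6)

    def test_3d_ramp_squared(self):
        radii = np.linspace(0, 1.0, 33)
        w = density_compensation(radii, 3, 100)
        prop = w[2:] / radii[2:] ** 2
        np.testing.assert_allclose(prop, prop[-1], rtol=1e-6)

    def test_ramp_portion_downweighted(self):
        # quadratic |k| growth on the ramp: k-space speed (and hence the
        # per-sample weight at fixed |k|) is reduced early in the readout
        s = np.linspace(0, 1, 33)
        rho = 0.3
        radii = np.where(s < rho, s**2 / (2 * rho), s - rho / 2)
        w = density_compensation(radii, 2, 100)
        per_k = w[1:] / radii[1:]  # proportional to d|k|/ds
        assert per_k[1] < per_k[-1] * 0.5

    def test_dc_weight_positive(self):
        w = density_compensation(np.linspace(0, 1, 33), 3, 10)
        assert w[0] > 0

    def test_zero_length_spoke(self):
        with pytest.raises(ValueError):
            density_compensation(np.zeros(5), 2, 10)


class TestGridRecon:
    def test_disk_matches_rendering_oracle(self, small_radial, grid3d):
        sc = Scene(cylinder_height=12.8)
        kd = acquire(sc, small_radial, seed=0)
        img = grid_recon(kd, "all", echo=0)
        oracle = np.abs(bandlimited_render(sc, 0.0, grid3d))
        xs = grid3d.coords()
        inside = xs[0] ** 2 + xs[1] ** 2 < (0.85 * sc.cylinder_radius) ** 2
        nrmse = np.sqrt(np.mean((img[inside] - oracle[inside]) ** 2)) / oracle[inside].mean()
        assert nrmse < 0.05

    def test_without_weights_fails_oracle(self, small_radial, grid3d):
        sc = Scene(cylinder_height=12.8)
        kd = acquire(sc, small_radial, seed=0)
        from voidlapse.gridding import GriddingOperator

        op = GriddingOperator(grid3d, kd.trajectory.reshape(-1, 3))
        img = np.abs(op.adjoint(kd.samples[0].reshape(-1)))
        oracle = np.abs(bandlimited_render(sc, 0.0, grid3d))
        xs = grid3d.coords()
        interior = xs[0] ** 2 + xs[1] ** 2 < (0.85 * sc.cylinder_radius) ** 2
        img = img / img[interior].mean()  # generous rescale; blur remains
        # include the cylinder edge, where the missing ramp filter blurs most
        mask = xs[0] ** 2 + xs[1] ** 2 < (1.1 * sc.cylinder_radius) ** 2
        nrmse = np.sqrt(np.mean((img[mask] - oracle[mask]) ** 2)) / oracle[mask].mean()
        assert nrmse > 0.15

    def test_void_centre_within_half_voxel(self, small_radial, grid3d, static_scene_3d):
        kd = acquire(static_scene_3d, small_radial, seed=0)
        img = grid_recon(kd, "all", echo=0)
        m = measure_spot(img, grid3d.index_of(static_scene_3d.particles[0].position0))
        err = np.linalg.norm(
            np.array(m.position)
            - np.array(grid3d.index_of(static_scene_3d.particles[0].position0))
        )
        assert err <= 0.5 + 1e-9

    def test_empty_object_reconstructs_to_zero(self, small_radial):
        sc = Scene(background_signal=0.0, cylinder_height=12.8)
        kd = acquire(sc, small_radial, seed=0)
        img = grid_recon(kd, "all", echo=0)
        assert np.abs(img).max() < 1e-10

    def test_empty_selection_rejected(self, small_radial, static_scene_3d):
        kd = acquire(static_scene_3d, small_radial, seed=0)
        with pytest.raises(ValueError):
            grid_recon(kd, [])


class TestEchoCombination:
    def test_equal_inputs_p_half(self):
        img = np.full((4, 4), 2.0)
        np.testing.assert_allclose(combine_echoes(img, img, p=-0.5), 8.0)

    @pytest.mark.parametrize(
        "i1,i2,p,expected",
        [(4.0, 0.0, -0.5, 4.0), (1.0, 1.0, 1.0, np.sqrt(2.0)), (1.0, 1.0, -0.5, 4.0)],
    )
    def test_closed_forms(self, i1, i2, p, expected):
        out = combine_echoes(np.array([i1]), np.array([i2]), p=p)
        assert out[0] == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            combine_echoes(np.array([1.0]), np.array([1.0]), p=-1)
        with pytest.raises(ValueError):
            combine_echoes(np.array([-0.1]), np.array([1.0]))

    def test_sos_forms(self):
        np.testing.assert_allclose(sos_combine(np.array([1.0]), np.array([1.0])), np.sqrt(2))
        np.testing.assert_allclose(sos_combine(np.array([3.0]), np.array([0.0])), 3.0)

    def test_weighted_deeper_void_than_sos(self):
        """When echo 2 carries the deeper void, the p=-0.5 combination keeps
        more relative void contrast than sum-of-squares."""
        sched = RadialSchedule(
            n_spokes=1800, interleave_factor=1, samples_per_spoke=25,
            matrix=(24,) * 3, fov=(12.8,) * 3, dual_echo=True, echo2_contrast_scale=1.4,
        )
        sc = Scene(
            particles=[Particle(0, np.array([2.0, 1.1, 0.6]), void_amplitude=0.5, void_sigma=0.25)],
            cylinder_height=12.8,
        )
        kd = acquire(sc, sched, seed=0)
        grid = ImageGrid(sched.matrix, sched.fov)
        idx = grid.index_of(sc.particles[0].position0)
        sl_w = measure_spot(grid_recon(kd, "all", echo="combined"), idx).sl
        sl_sos = measure_spot(grid_recon(kd, "all", echo="sos"), idx).sl
        assert sl_w > sl_sos


class TestCompressedSensing:
    def test_lambda_zero_equals_gridding(self, small_radial, static_scene_3d):
        kd = acquire(static_scene_3d, small_radial, seed=0)
        series = cs_recon(kd, 5, CSConfig(lambda_percent=0.0), echo=0)
        for s in range(5):
            us = grid_recon(kd, (5, s), echo=0)
            nrmse = np.linalg.norm(series.frames[s] - us) / np.linalg.norm(us)
            assert nrmse < 0.01

    def test_tv_monotone_in_lambda(self, small_radial):
        sc = Scene(
            particles=[Particle(0, np.array([2.0, 1.1, 0.6]), void_amplitude=0.5, void_sigma=0.25)],
            cylinder_height=12.8,
            noise_sigma=0.4,
        )
        kd = acquire(sc, small_radial, seed=0)
        tvs = []
        for lam in (0.0, 1.0, 4.0):
            frames = np.stack(cs_recon(kd, 5, CSConfig(lambda_percent=lam), echo=0).frames)
            tvs.append(np.sum(np.abs(np.diff(frames, axis=0))))
        assert tvs[0] >= tvs[1] >= tvs[2]
        assert tvs[2] < tvs[0]

    def test_cs_denoises_relative_to_us(self, small_radial):
        sc = Scene(cylinder_height=12.8, noise_sigma=0.55)
        kd = acquire(sc, small_radial, seed=1)
        grid = ImageGrid(small_radial.matrix, small_radial.fov)
        xs = grid.coords()
        air = xs[0] ** 2 + xs[1] ** 2 > (1.25 * sc.cylinder_radius) ** 2
        sd_us = np.mean([np.std(grid_recon(kd, (5, s), echo=0)[air]) for s in range(5)])
        series = cs_recon(kd, 5, CSConfig(lambda_percent=2.0), echo=0)
        sd_cs = np.mean([np.std(f[air]) for f in series.frames])
        assert sd_cs < sd_us

    def test_frame_timing_metadata(self, small_radial, static_scene_3d):
        kd = acquire(static_scene_3d, small_radial, seed=0)
        series = cs_recon(kd, 5, CSConfig(lambda_percent=0.0), echo=0)
        assert len(series) == 5
        assert series.acceleration == 5
        durations = [d for (_, d) in series.frame_times]
        assert durations[0] == pytest.approx(small_radial.n_spokes * small_radial.tr_ms / 1000 / 5)


class TestMip:
    def test_uniform_volume_projects_to_zero(self):
        mips = mip_render(np.full((8, 8, 8), 3.0))
        for m in mips:
            np.testing.assert_allclose(m, 0.0)

    def test_single_void_positions(self):
        vol = np.ones((8, 8, 8))
        vol[2, 5, 6] = 0.2
        mips = mip_render(vol)
        assert np.unravel_index(np.argmax(mips[0]), mips[0].shape) == (5, 6)
        assert np.unravel_index(np.argmax(mips[1]), mips[1].shape) == (2, 6)
        assert np.unravel_index(np.argmax(mips[2]), mips[2].shape) == (2, 5)

    def test_two_voids_along_axis(self):
        vol = np.ones((8, 8, 8))
        vol[1, 4, 4] = 0.0
        vol[6, 4, 4] = 0.0
        mips = mip_render(vol)
        # projecting along x merges them; the other views separate them
        assert (mips[0] > 0.5).sum() == 1
        assert (mips[1] > 0.5).sum() == 2
        assert (mips[2] > 0.5).sum() == 2

    def test_rejects_2d(self):
        with pytest.raises(ValueError):
            mip_render(np.ones((4, 4)))
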