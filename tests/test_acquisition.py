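"""Sampling schedules, interleaving, timing and acquisition simulation."""

import numpy as np
import pytest

from voidlapse.acquisition import (
    CartesianSchedule,
    KSpaceData,
    RadialSchedule,
    acquire,
    cartesian_frame_duration,
    generate_spoke_directions,
    interleave_order,
    radial_frame_duration,
)
from voidlapse.phantom import Particle, Scene, bandlimited_render, ImageGrid
from voidlapse.reconstruction import cartesian_recon


def _nn_angles(dirs):
    cosm = np.clip(dirs @ dirs.T, -1, 1)
    np.fill_diagonal(cosm, -1)
    return np.arccos(cosm.max(axis=1))


class TestSpokeDirections:
    def test_single_direction_is_unit(self):
        d = generate_spoke_directions(1)
        assert d.shape == (1, 3)
        assert np.linalg.norm(d[0]) == pytest.approx(1.0)

    def test_quasi_uniform_spacing(self):
        ang = _nn_angles(generate_spoke_directions(1000))
        assert np.std(ang) / np.mean(ang) < 0.5

    @pytest.mark.parametrize("n", [100, 1000])
    def test_directional_balance(self, n):
        mean = generate_spoke_directions(n).mean(axis=0)
        assert np.linalg.norm(mean) < 0.05

    def test_deterministic(self):
        np.testing.assert_array_equal(
            generate_spoke_directions(64), generate_spoke_directions(64)
        )

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            generate_spoke_directions(0)


class TestInterleaving:
    def test_reference_protocol_counts(self):
        order, ids = interleave_order(120188, 20)
        counts = np.bincount(ids[ids >= 0])
        assert np.all(counts == 6009)
        assert np.sum(ids == -1) == 120188 - 20 * 6009  # 8 remainder spokes

    def test_identity_grouping(self):
        order, ids = interleave_order(10, 1)
        assert np.all(ids == 0)
        np.testing.assert_array_equal(np.sort(order), np.arange(10))

    def test_union_is_partition(self):
        order, ids = interleave_order(997, 7)
        np.testing.assert_array_equal(np.sort(order), np.arange(997))
        assert len(set(order.tolist())) == 997

    def test_interleaves_stay_uniform(self):
        """Each interleave's nearest-neighbour angle statistics stay within
        2x of a freshly generated direction set of the same size."""
        n, f = 100, 5
        dirs = generate_spoke_directions(n)
        _, ids = interleave_order(n, f)
        fresh = _nn_angles(generate_spoke_directions(n // f)).mean()
        for i in range(f):
            sub = _nn_angles(dirs[ids == i]).mean()
            assert fresh / 2 < sub < fresh * 2

    def test_bad_factor(self):
        with pytest.raises(ValueError):
            interleave_order(10, 11)


class TestTiming:
    def test_cartesian_arithmetic(self):
        sched = CartesianSchedule(matrix=(256, 256), tr_ms=12.0, averages=32)
        assert cartesian_frame_duration(sched) == pytest.approx(98.304)

    def test_cartesian_with_overhead(self):
        # dummy-scan overhead reproduces the protocol's printed 1:42.85 min
        sched = CartesianSchedule(
            matrix=(256, 256), tr_ms=12.0, averages=32, overhead_s=4.546
        )
        assert cartesian_frame_duration(sched) == pytest.approx(102.85)

    def test_single_line(self):
        sched = CartesianSchedule(matrix=(8, 1), tr_ms=7.0, averages=1)
        assert cartesian_frame_duration(sched) == pytest.approx(0.007)

    def test_radial_reference_durations(self):
        sched = RadialSchedule(n_spokes=120188, interleave_factor=20, tr_ms=4.0)
        assert radial_frame_duration(sched, 1) == pytest.approx(480.752)
        assert radial_frame_duration(sched, 5) == pytest.approx(96.1504)
        assert sched.spokes_per_interleave == 6009

    def test_radial_trivial(self):
        sched = RadialSchedule(n_spokes=100, interleave_factor=10, tr_ms=10.0)
        assert radial_frame_duration(sched, 1) == pytest.approx(1.0)

    def test_radial_invalid_subframes(self):
        sched = RadialSchedule(n_spokes=100, interleave_factor=10, tr_ms=10.0)
        with pytest.raises(ValueError):
            radial_frame_duration(sched, 3)  # 3 does not divide f = 10


class TestAcquire:
    def test_noiseless_static_is_deterministic(self, small_cartesian, static_scene_2d):
        k1 = acquire(static_scene_2d, small_cartesian, seed=0)
        k2 = acquire(static_scene_2d, small_cartesian, seed=99)
        np.testing.assert_array_equal(k1.samples, k2.samples)

    def test_same_seed_reproducible_with_noise(self, small_cartesian):
        sc = Scene(particles=[Particle(0, np.array([1.0, 0.0]))], noise_sigma=0.3)
        k1 = acquire(sc, small_cartesian, seed=5)
        k2 = acquire(sc, small_cartesian, seed=5)
        np.testing.assert_array_equal(k1.samples, k2.samples)

    def test_rotation_changes_samples(self, small_cartesian):
        p = [Particle(0, np.array([2.5, 0.0]))]
        k_stat = acquire(Scene(particles=p), small_cartesian, seed=0)
        k_rot = acquire(Scene(particles=p, omega_rpm=0.05), small_cartesian, seed=0)
        assert not np.allclose(k_stat.samples, k_rot.samples)

    def test_timestamps_increase_in_acquisition_order(self, small_radial, static_scene_3d):
        kd = acquire(static_scene_3d, small_radial, seed=0)
        ts = kd.timestamps[small_radial.acquisition_order]
        assert np.all(np.diff(ts) > 0)

    def test_static_recon_matches_snapshot_oracle(self, small_cartesian, grid2d):
        """Acquisition of a frozen scene reconstructs to the single-snapshot
        dense-FFT rendering (noise floor only)."""
        sc = Scene(particles=[Particle(0, np.array([2.0, 1.1]))], noise_sigma=0.0)
        img = cartesian_recon(acquire(sc, small_cartesian, seed=0))
        oracle = np.abs(bandlimited_render(sc, 0.0, grid2d))
        np.testing.assert_allclose(img, oracle, atol=1e-9)

    def test_dual_echo_second_echo_deeper(self, small_radial, static_scene_3d):
        sched = RadialSchedule(
            n_spokes=200, interleave_factor=1, samples_per_spoke=25,
            matrix=(24,) * 3, fov=(12.8,) * 3, dual_echo=True, echo2_contrast_scale=1.3,
        )
        kd = acquire(static_scene_3d, sched, seed=0)
        assert kd.n_echoes == 2
        # deeper voids -> smaller DC magnitude on echo 2
        dc_spoke = np.abs(kd.samples[:, :, 0]).mean(axis=1)
        assert dc_spoke[1] < dc_spoke[0]

    def test_hdf5_round_trip(self, tmp_path, small_radial, static_scene_3d):
        kd = acquire(static_scene_3d, small_radial, seed=3)
        kd.to_hdf5(tmp_path / "k.h5")
        back = KSpaceData.from_hdf5(tmp_path / "k.h5")
        np.testing.assert_array_equal(back.samples, kd.samples)
        np.testing.assert_array_equal(back.trajectory, kd.trajectory)
        assert isinstance(back.schedule, RadialSchedule)
        assert back.schedule.n_spokes == small_radial.n_spokes
        assert back.noise_sigma == kd.noise_sigma
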