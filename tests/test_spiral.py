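import numpy as np
import pytest

from spiralcine.spiral import (
    SpiralKSpace,
    bin_segmented_cine,
    dc_gate,
    dc_navigator_signal,
    frame_arm_schedule,
    make_spiral_trajectory,
    ndft2,
    sample_kspace,
    thin_arm_schedule,
)
from spiralcine.synthetic import CineImage, CoilMaps, PhantomConfig, generate_phantom


class TestTrajectory:
    def test_single_arm_has_dc_sample(self):
        traj = make_spiral_trajectory(n_arms_full=1, grid_size=32, rotation_states=1)
        assert traj.arm_coords.shape[0] == 1
        assert np.allclose(traj.arm_coords[0, 0], 0.0)

    def test_radius_monotone_and_bounded(self):
        traj = make_spiral_trajectory(104, grid_size=96)
        r = np.linalg.norm(traj.arm_coords, axis=-1)
        assert np.max(r) < 0.5
        assert np.all(np.diff(r, axis=1) >= -1e-12)

    def test_rotation_subsets_disjoint_union(self):
        # the 8 per-frame 13-arm subsets partition the 104 arms
        traj = make_spiral_trajectory(104, grid_size=96)
        sched = frame_arm_schedule(traj, 8 * traj.rotation_period_frames)
        subsets = [set(sched[s * traj.rotation_period_frames].tolist()) for s in range(8)]
        assert all(len(s) == 13 for s in subsets)
        union = set().union(*subsets)
        assert union == set(range(104))
        for i in range(8):
            for j in range(i + 1, 8):
                assert not (subsets[i] & subsets[j])

    def test_arms_are_equiangular_copies(self):
        traj = make_spiral_trajectory(8, grid_size=32, rotation_states=2)
        base = traj.arm_coords[0]
        for i in range(8):
            a = 2 * np.pi * i / 8
            rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            np.testing.assert_allclose(traj.arm_coords[i], base @ rot.T, atol=1e-12)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            make_spiral_trajectory(13, grid_size=0)


class TestSchedule:
    def test_rotation_every_ten_frames(self):
        traj = make_spiral_trajectory(104, grid_size=96, rotation_period_frames=10)
        sched = frame_arm_schedule(traj, 25)
        for f in range(1, 10):
            assert np.array_equal(sched[f], sched[0])
        assert not np.array_equal(sched[10], sched[0])
        for f in range(11, 20):
            assert np.array_equal(sched[f], sched[10])

    def test_frame_arms_equiangular_2pi_over_13(self):
        traj = make_spiral_trajectory(104, grid_size=96)
        sched = frame_arm_schedule(traj, 40)
        for f in (0, 15, 33):
            angles = np.sort(2 * np.pi * sched[f] / 104)
            gaps = np.diff(np.concatenate([angles, [angles[0] + 2 * np.pi]]))
            np.testing.assert_allclose(gaps, 2 * np.pi / 13, atol=1e-12)

    def test_no_rotation_states_means_static_schedule(self):
        traj = make_spiral_trajectory(13, grid_size=32, rotation_states=1)
        sched = frame_arm_schedule(traj, 7)
        for f in range(7):
            assert np.array_equal(sched[f], sched[0])

    def test_thin_keeps_every_second_arm(self):
        traj = make_spiral_trajectory(104, grid_size=96)
        sched = frame_arm_schedule(traj, 3)
        thin = thin_arm_schedule(sched, 2)
        for full, seven in zip(sched, thin):
            assert np.array_equal(seven, full[::2])
            assert len(seven) == 7


class TestSampleKspace:
    def test_point_source_flat_spectrum(self):
        g = 16
        img = np.zeros((1, g, g), dtype=complex)
        img[0, g // 2, g // 2] = 3.0  # centered point source
        maps = CoilMaps(np.ones((1, g, g), dtype=complex))
        traj = make_spiral_trajectory(4, grid_size=g, rotation_states=1)
        ksp = sample_kspace(
            CineImage(img), maps, traj, [np.arange(4)], noise_sigma=0.0
        )
        np.testing.assert_allclose(np.abs(ksp.samples[0]), 3.0 / g, rtol=1e-12)

    def test_matches_dense_dft_oracle(self, rng):
        g = 16
        img = rng.standard_normal((1, g, g)) + 1j * rng.standard_normal((1, g, g))
        maps_data = rng.standard_normal((2, g, g)) + 1j * rng.standard_normal((2, g, g))
        traj = make_spiral_trajectory(4, grid_size=g, rotation_states=1)
        sched = [np.arange(4)]
        ksp = sample_kspace(CineImage(img), CoilMaps(maps_data), traj, sched, 0.0)
        coords = traj.arm_coords.reshape(-1, 2)
        p = np.arange(g) - g // 2
        for c in range(2):
            coil_img = maps_data[c] * img[0]
            oracle = np.array(
                [
                    np.sum(
                        coil_img
                        * np.exp(-2j * np.pi * (kx * p[None, :] + ky * p[:, None]))
                    )
                    / g
                    for kx, ky in coords
                ]
            )
            err = np.abs(ksp.samples[0][c] - oracle).max() / np.abs(oracle).max()
            assert err < 1e-6

    def test_temporal_footprint_13_and_7_arms(self):
        # 13 arms x TR(=48/13 ms) = 48 ms; dropping every second arm -> 7 arms, ~26 ms
        tr = 48e-3 / 13
        assert 13 * tr == pytest.approx(48e-3)
        traj = make_spiral_trajectory(104, grid_size=96)
        sched = thin_arm_schedule(frame_arm_schedule(traj, 1), 2)
        assert len(sched[0]) == 7
        assert 7 * tr == pytest.approx(26e-3, rel=0.01)

    def test_mismatched_grid_rejected(self, tiny_phantom):
        maps = CoilMaps(np.ones((1, 32, 32), dtype=complex))
        traj = make_spiral_trajectory(4, grid_size=32, rotation_states=1)
        with pytest.raises(ValueError):
            sample_kspace(tiny_phantom, maps, traj, [np.arange(4)] * tiny_phantom.n_frames)


class TestDCGate:
    def test_uniform_periodic_fill(self):
        # perfectly periodic signal, n_phases divides the period
        p, cycles, n_phases = 24, 6, 4
        t = np.arange(p * cycles + 1)
        dc = 1.0 + 0.3 * np.cos(2 * np.pi * t / p)
        g = dc_gate(dc, n_phases=n_phases, arms_per_frame=1)
        counts = np.bincount(g.phase_assignment[g.phase_assignment >= 0], minlength=n_phases)
        assert np.all(counts == counts[0])
        assert counts[0] == (len(g.trigger_indices) - 1) * p // n_phases

    def test_triggers_match_generator_truth_within_one_arm(self):
        cfg = PhantomConfig(
            grid_size=64, crop_size=48, n_frames_per_cycle=20, n_cycles=8,
            n_coils=4, contraction_amplitude=0.35, seed=3,
        )
        dc, truth = dc_navigator_signal(cfg, arms_per_frame=13)
        g = dc_gate(dc, n_phases=20, arms_per_frame=13)
        assert len(g.trigger_indices) >= 6
        for t in g.trigger_indices:
            assert np.min(np.abs(truth - t)) <= 1

    def test_too_few_triggers_raises(self):
        with pytest.raises(ValueError, match="cannot gate"):
            dc_gate(np.ones(50), n_phases=4, arms_per_frame=1)


def _simulate_segmented(seed=0, rr_jitter=0.0, n_cycles=9):
    from spiralcine.pipeline import ExperimentConfig, build_world, acquire

    cfg = ExperimentConfig(
        grid_size=64, crop_size=48, n_frames_per_cycle=4, n_cycles=n_cycles,
        n_coils=3, rotation_period_frames=4, seed=seed, noise_sigma=0.0,
    )
    world = build_world(cfg, rr_jitter=rr_jitter)
    ksp, schedule = acquire(world, cfg.n_frames_per_cycle * n_cycles)
    return cfg, world, ksp


class TestBinning:
    def test_eight_regular_cycles_give_104_arms_per_phase(self):
        cfg, world, ksp = _simulate_segmented(n_cycles=10)
        g = dc_gate(ksp.dc_signal, n_phases=4, arms_per_frame=13)
        binned = bin_segmented_cine(ksp, g)
        assert binned.n_frames == 4
        for ids in binned.arm_ids:
            assert len(set(ids.tolist())) == 104

    def test_single_cycle_identity_regrouping(self):
        # one cycle, one phase per frame, known gating -> regrouping only
        cfg, world, ksp = _simulate_segmented(n_cycles=2)
        n_arms = 8 * 13
        from spiralcine.spiral import GatingResult

        gating = GatingResult(
            trigger_indices=np.array([0, 4 * 13]),
            phase_assignment=np.concatenate(
                [np.repeat(np.arange(4), 13), np.full(4 * 13, -1)]
            ),
            n_phases=4,
            rejected_arms=np.arange(4 * 13, n_arms),
        )
        binned = bin_segmented_cine(ksp, gating)
        for p in range(4):
            assert np.array_equal(np.sort(binned.arm_ids[p]), np.sort(ksp.arm_ids[p]))
            np.testing.assert_allclose(
                np.sort(binned.samples[p].ravel()), np.sort(ksp.samples[p].ravel())
            )

    def test_empty_phase_bin_raises_with_bin_name(self):
        cfg, world, ksp = _simulate_segmented(n_cycles=2)
        from spiralcine.spiral import GatingResult

        gating = GatingResult(
            trigger_indices=np.array([0, 52]),
            phase_assignment=np.where(np.arange(104) < 52, 0, -1),
            n_phases=3,
            rejected_arms=np.arange(52, 104),
        )
        with pytest.raises(ValueError, match="phase bin 1"):
            bin_segmented_cine(ksp, gating)

    def test_rr_jitter_blurs_segmented_recon(self):
        from spiralcine.pipeline import grog_calibrate, grid_frames, segmented_recon
        from spiralcine.evaluation import prepare_for_metrics, compute_metrics
        from spiralcine.synthetic import CineImage as CI

        ssims = {}
        for jitter in (0.0, 0.12):
            cfg, world, ksp = _simulate_segmented(seed=4, rr_jitter=jitter, n_cycles=10)
            g = dc_gate(ksp.dc_signal, n_phases=4, arms_per_frame=13)
            binned = bin_segmented_cine(ksp, g)
            kern = grog_calibrate(world, ksp)
            gridded = grid_frames(world, binned, kern)
            rec = segmented_recon(world, gridded)
            ref = CI(world.phantom.data[: rec.n_frames])
            m = compute_metrics(prepare_for_metrics(rec, ref, crop=40))
            ssims[jitter] = m.ssim
        assert ssims[0.12] < ssims[0.0]
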