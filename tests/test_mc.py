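"""Monte Carlo sampler: detailed balance, stationary states, determinism."""

import math

import numpy as np
import pytest

from patchnet import (Configuration, ModelParams, MoveSchedule, Particle,
                      run_mc, total_energy)
from patchnet import _kernels
from patchnet.mc import state_flip_acceptance


def quick_params(n=40, phi=0.1, **kw):
    return ModelParams.for_area_fraction(phi, n, **kw)


class TestStateFlipAcceptance:
    def test_isolated_closed_to_open_favoured(self):
        p = ModelParams(p_open=0.8)
        assert state_flip_acceptance(1, 0.0, p) == 1.0

    def test_bonded_closed_to_open_pays_bond_energy(self):
        p = ModelParams(p_open=0.8)
        # breaking one bond of 8 kT: min(1, (0.8/0.2) e^-8)
        assert state_flip_acceptance(1, 8.0, p) == \
            pytest.approx(4.0 * math.exp(-8.0))

    def test_open_to_closed_with_energy_gain(self):
        p = ModelParams(p_open=0.8)
        assert state_flip_acceptance(0, -8.0, p) == 1.0

    @pytest.mark.parametrize("p_open, state, expected", [
        (0.0, 1, 0.0),   # flip toward open, which has zero weight
        (0.0, 0, 1.0),   # escape the zero-weight state
        (1.0, 0, 0.0),
        (1.0, 1, 1.0),
    ])
    def test_degenerate_weights_no_division_error(self, p_open, state, expected):
        p = ModelParams(p_open=p_open)
        assert state_flip_acceptance(state, 0.0, p) == expected


class TestDeterminism:
    def test_identical_seeds_identical_trajectories(self):
        params = quick_params(30, epsilon=6.0)
        a = run_mc(params, n_sweeps=2_000, record_every=500, seed=42)
        b = run_mc(params, n_sweeps=2_000, record_every=500, seed=42)
        for fa, fb in zip(a.frames, b.frames):
            assert np.array_equal(fa.pos, fb.pos)
            assert np.array_equal(fa.orient, fb.orient)
            assert np.array_equal(fa.states, fb.states)

    def test_trajectory_files_byte_identical(self, tmp_path):
        from patchnet.io import write_trajectory

        params = quick_params(20, epsilon=4.0)
        pa, pb = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        write_trajectory(run_mc(params, n_sweeps=1_000, record_every=500,
                                seed=7), pa)
        write_trajectory(run_mc(params, n_sweeps=1_000, record_every=500,
                                seed=7), pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_differ(self):
        params = quick_params(20, epsilon=4.0)
        a = run_mc(params, n_sweeps=1_000, record_every=1_000, seed=1)
        b = run_mc(params, n_sweeps=1_000, record_every=1_000, seed=2)
        assert not np.array_equal(a.frames[-1].pos, b.frames[-1].pos)


class TestStationaryStates:
    @pytest.mark.parametrize("p_open", [0.2, 0.5, 0.8])
    def test_open_fraction_matches_p_open_at_zero_coupling(self, p_open):
        """With epsilon = 0 the patch states decouple from geometry and the
        stationary open fraction must equal p_open."""
        params = quick_params(64, epsilon=0.0, p_open=p_open)
        traj = run_mc(params, n_sweeps=6_000, record_every=200, seed=3)
        fracs = [float(np.mean(fr.states == 0)) for fr in traj.frames[10:]]
        se = np.std(fracs, ddof=1) / math.sqrt(len(fracs))
        assert abs(np.mean(fracs) - p_open) < 3 * max(se, 1e-3)

    def test_two_particle_bonded_fraction_matches_quadrature_oracle(self):
        """Detailed-balance check: the bonded-frame fraction of a 2-particle
        system equals the configurational-integral prediction (independent
        quadrature over separation, orientations and patch states)."""
        L = 6.0
        eps, p_open, theta = 6.0, 0.2, 0.44
        params = ModelParams(epsilon=eps, p_open=p_open, theta_pw=theta,
                             box_side=L, n_particles=2,
                             normalize_patch_entropy=False)

        # oracle: relative position uniform over the box; angular acceptance
        # of one particle by quadrature; patch states summed exactly
        sigma, delta = params.sigma, params.delta
        thetas = np.linspace(0.0, 2 * np.pi, 4001)[:-1]
        aligned = np.zeros_like(thetas, dtype=bool)
        for k in range(3):
            dev = np.abs(np.angle(np.exp(1j * (thetas + k * 2 * np.pi / 3))))
            aligned |= dev < theta
        q_side = float(np.mean(aligned))
        q = q_side**2
        f_bond = (1 - p_open) ** 2 * math.exp(eps)
        f_nobond = 1 - (1 - p_open) ** 2
        a_shell = math.pi * ((sigma + delta) ** 2 - sigma**2)
        area = L * L
        z = (area - math.pi * (sigma + delta) ** 2) \
            + a_shell * (q * (f_bond + f_nobond) + (1 - q))
        p_bond_oracle = a_shell * q * f_bond / z

        traj = run_mc(params, n_sweeps=400_000, record_every=400, seed=5,
                      schedule=MoveSchedule(cluster_moves=False,
                                            f_translate=0.45, f_rotate=0.25,
                                            f_flip=0.3, f_cluster=0.0))
        bonded = np.array([
            1.0 if total_energy(fr, params) < 0 else 0.0
            for fr in traj.frames[50:]
        ])
        blocks = bonded[:len(bonded) // 10 * 10].reshape(10, -1).mean(axis=1)
        se = float(np.std(blocks, ddof=1) / math.sqrt(len(blocks)))
        assert abs(bonded.mean() - p_bond_oracle) < 3 * max(se, 5e-3)

    def test_cluster_moves_do_not_shift_equilibrium(self):
        """Cluster moves change kinetics, not the stationary distribution:
        mean energies with and without them agree within combined errors."""
        params = quick_params(40, phi=0.15, epsilon=4.0, p_open=0.3,
                              normalize_patch_entropy=False)

        def mean_energy(cluster, seed):
            sched = MoveSchedule() if cluster else MoveSchedule(
                f_translate=0.5, f_rotate=0.2, f_flip=0.3, f_cluster=0.0,
                cluster_moves=False)
            traj = run_mc(params, schedule=sched, n_sweeps=20_000,
                          record_every=1_000, seed=seed)
            return float(traj.observables.energy.tail(10).mean())

        with_cl = [mean_energy(True, s) for s in range(8)]
        without = [mean_energy(False, s + 100) for s in range(8)]
        se = math.sqrt(np.var(with_cl, ddof=1) / 8 + np.var(without, ddof=1) / 8)
        assert abs(np.mean(with_cl) - np.mean(without)) < 3 * max(se, 1e-6)


class TestTrajectoryInvariants:
    def test_energy_bookkeeping_matches_recomputation(self):
        params = quick_params(50, epsilon=8.0, p_open=0.5)
        traj = run_mc(params, n_sweeps=20_000, record_every=1_000, seed=11)
        obs = traj.observables
        assert np.allclose(obs.energy, obs.energy_check, atol=1e-8 * 50)

    def test_frames_respect_hard_core_and_single_bond_per_patch(self):
        params = quick_params(60, epsilon=10.0, p_open=0.3)
        traj = run_mc(params, n_sweeps=10_000, record_every=1_000, seed=13)
        for fr in traj.frames:
            fr.check_no_overlap(params.sigma)
            bonds = _kernels.list_bonds(
                fr.pos[:, 0].copy(), fr.pos[:, 1].copy(), fr.orient.copy(),
                fr.states.astype(np.int8), fr.box_side, params.sigma,
                params.delta, params.theta_pw)
            used = set()
            for i, j, a, b in bonds:
                assert (i, a) not in used and (j, b) not in used
                used.add((i, a))
                used.add((j, b))

    def test_zero_coupling_stays_at_zero_energy(self):
        params = quick_params(40, epsilon=0.0)
        traj = run_mc(params, n_sweeps=3_000, record_every=1_000, seed=1)
        assert np.allclose(traj.observables.energy, 0.0)

    def test_assembly_smoke_always_closed_patches(self):
        """With p_open = 0 and strong attraction, large bonded clusters
        (>= 24 particles) appear within 1e5 sweeps at area fraction 0.1."""
        from patchnet.morphology import analyze_frame

        params = quick_params(100, epsilon=8.0, p_open=0.0)
        traj = run_mc(params, n_sweeps=100_000, record_every=20_000, seed=2)
        rep = analyze_frame(traj.frames[-1], params=params)
        big = rep.largest_island
        assert big is not None and big.island.size >= 24


class TestDeposition:
    def test_rate_zero_keeps_count_constant(self):
        params = quick_params(30, epsilon=4.0)
        traj = run_mc(params, n_sweeps=2_000, record_every=500, seed=1,
                      schedule=MoveSchedule(deposition_rate=0.0))
        assert set(traj.observables.n_particles) == {30}

    def test_poisson_insertion_count_in_empty_box(self):
        params = ModelParams.for_area_fraction(0.001, 1, epsilon=0.0)
        params = params.with_(n_particles=0, box_side=40.0)
        rate, sweeps = 0.02, 5_000
        traj = run_mc(params, n_sweeps=sweeps, record_every=500, seed=4,
                      schedule=MoveSchedule(deposition_rate=rate))
        final = traj.observables.n_particles.iloc[-1]
        mean = rate * sweeps
        assert abs(final - mean) < 4 * math.sqrt(mean)

    def test_inserted_particles_respect_hard_core(self):
        params = quick_params(20, epsilon=6.0)
        traj = run_mc(params, n_sweeps=4_000, record_every=1_000, seed=6,
                      schedule=MoveSchedule(deposition_rate=0.01))
        for fr in traj.frames:
            fr.check_no_overlap(params.sigma)
        assert traj.observables.n_particles.iloc[-1] > 20


class TestScheduleValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MoveSchedule(f_translate=0.5, f_rotate=0.5, f_flip=0.5,
                         f_cluster=0.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            MoveSchedule(deposition_rate=-1.0)

    def test_unreachable_random_init_raises(self):
        with pytest.raises(RuntimeError, match="area fraction"):
            run_mc(ModelParams.for_area_fraction(0.85, 60),
                   n_sweeps=100, record_every=100, seed=0)
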