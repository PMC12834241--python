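"""Nucleus force field and Brownian dynamics."""

from dataclasses import replace

import numpy as np
import pytest

from orgnuc.nucleus import (
    NucleusParams,
    MotorConfig,
    NucleusState,
    assemble_state,
    soft_core_force,
    total_forces,
    potential_energy,
    step_nucleus,
    apply_plate_compression,
    run_compression,
    assign_motors,
    motor_forces,
    motor_turnover,
)
from orgnuc.nucleus.dynamics import InstabilityError, plate_positions
from orgnuc.nucleus.forces import chain_outside_fraction
from orgnuc.nucleus.state import stream_rng
from orgnuc.protocols import constant_rate_protocol


def free_chain_state(N: int, seed: int, params: NucleusParams) -> NucleusState:
    """A bare Rouse chain (no shell, crosslinks or linkages)."""
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((N - 1, 3))
    steps *= params.sigma / np.linalg.norm(steps, axis=1, keepdims=True)
    chain = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    empty2 = np.empty((0, 2), dtype=np.int64)
    bonds = np.column_stack([np.arange(N - 1), np.arange(1, N)]).astype(np.int64)
    rest = np.linalg.norm(chain[1:] - chain[:-1], axis=1)
    return NucleusState(
        chain=chain, lamina=np.empty((0, 3)),
        chain_bonds=bonds, crosslink_bonds=empty2,
        lamina_bonds=empty2, linkage_bonds=empty2,
        chain_rest=rest, crosslink_rest=np.empty(0),
        lamina_rest=np.empty(0), linkage_rest=np.empty(0),
    )


class TestSoftCore:
    def test_zero_at_and_beyond_contact(self):
        assert np.allclose(soft_core_force([0, 0, 0], [0.1, 0, 0], 0.1, 140.0), 0)
        assert np.allclose(soft_core_force([0, 0, 0], [0.15, 0, 0], 0.1, 140.0), 0)

    def test_half_overlap_magnitude(self):
        # |r| = 0.5 sigma, K_ex = 140 -> repulsive force of magnitude 70 sigma
        sigma = 0.1
        f = soft_core_force([0, 0, 0], [0.5 * sigma, 0, 0], sigma, 140.0)
        assert np.linalg.norm(f) == pytest.approx(70.0 * sigma)
        assert f[0] < 0  # pushes i away from j

    def test_antisymmetry(self):
        a, b = np.array([0.0, 0.01, 0.02]), np.array([0.03, 0.0, 0.0])
        fab = soft_core_force(a, b, 0.1, 140.0)
        fba = soft_core_force(b, a, 0.1, 140.0)
        assert np.allclose(fab, -fba)

    def test_coincident_fallback_is_deterministic(self):
        f1 = soft_core_force([1, 1, 1], [1, 1, 1], 0.1, 140.0)
        f2 = soft_core_force([1, 1, 1], [1, 1, 1], 0.1, 140.0)
        assert np.allclose(f1, f2)
        assert np.linalg.norm(f1) == pytest.approx(140.0 * 0.1)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            soft_core_force([0, 0, 0], [1, 0, 0], 0.0, 1.0)


class TestForceConsistency:
    def test_forces_match_finite_differences(self, micro_state, micro_nucleus_params):
        p = micro_nucleus_params
        rng = np.random.default_rng(0)
        st = micro_state.copy()
        st.set_positions(st.positions + 0.02 * rng.standard_normal((st.N + st.M, 3)))
        walls = (-0.5, 0.5)
        F = total_forces(st, p, walls=walls)
        h = 1e-6
        for i in rng.choice(st.N + st.M, 6, replace=False):
            for d in range(3):
                up = st.copy()
                q = up.positions
                q[i, d] += h
                up.set_positions(q)
                dn = st.copy()
                q = dn.positions
                q[i, d] -= h
                dn.set_positions(q)
                fd = -(potential_energy(up, p, walls) - potential_energy(dn, p, walls)) / (2 * h)
                assert fd == pytest.approx(F[i, d], rel=1e-4, abs=1e-4)

    def test_newtons_third_law(self, micro_state, micro_nucleus_params):
        rng = np.random.default_rng(1)
        st = micro_state.copy()
        st.set_positions(st.positions + 0.05 * rng.standard_normal((st.N + st.M, 3)))
        F = total_forces(st, micro_nucleus_params)  # internal only
        assert np.abs(F.sum(axis=0)).max() < 1e-10

    def test_built_state_is_nearly_force_free(self, micro_state, micro_nucleus_params):
        # as-built rest lengths: only residual soft-core overlaps remain,
        # tiny against the ~1e2 thermal force scale
        F = total_forces(micro_state, micro_nucleus_params)
        assert np.abs(F).max() < 5.0


class TestWalls:
    def test_no_penetration_no_force(self, micro_state, micro_nucleus_params):
        proto = constant_rate_protocol(0.4, 10.0)
        F = apply_plate_compression(micro_state, proto, 0.0, micro_nucleus_params)
        assert np.abs(F).max() == 0.0

    def test_spring_law_on_lamina(self, micro_state, micro_nucleus_params):
        p = micro_nucleus_params
        st = micro_state.copy()
        proto = constant_rate_protocol(0.0, 10.0)
        z_top = plate_positions(st, proto, 0.0)[1]
        st.lamina = st.lamina.copy()
        k = int(np.argmax(st.lamina[:, 2]))
        st.lamina[k, 2] = z_top + 0.1
        F = apply_plate_compression(st, proto, 0.0, p, gap0=2 * z_top)
        assert F[st.N + k, 2] == pytest.approx(-0.1 * p.k_wall)

    def test_chromatin_feels_no_wall(self, micro_state, micro_nucleus_params):
        p = micro_nucleus_params
        st = micro_state.copy()
        st.chain = st.chain.copy()
        st.chain[0, 2] = 100.0  # far beyond any plate
        proto = constant_rate_protocol(0.0, 10.0)
        F = apply_plate_compression(st, proto, 0.0, p)
        assert np.abs(F[: st.N]).max() == 0.0


class TestDynamics:
    def test_static_without_noise(self, micro_state, micro_nucleus_params):
        p = replace(micro_nucleus_params, D_Teff=0.0)
        rng = np.random.default_rng(0)
        st = micro_state.copy()
        start = st.positions.copy()
        for _ in range(50):
            st = step_nucleus(st, p, rng, in_place=True)
        # relaxation only: drift stays well below a monomer radius
        assert np.abs(st.positions - start).max() < p.r_c

    def test_free_monomer_diffusion(self):
        # no interactions: MSD/t -> 6 D within 10%
        p = NucleusParams(N=2, M_lam=0, N_C=0, N_L=0, K=0.0, K_ex=0.0, D_Teff=1.0)
        st = free_chain_state(2, 0, p)
        st.chain_rest[:] = 0.0
        proto = constant_rate_protocol(0.0, 1.0)
        msds = []
        for rep in range(60):
            traj = run_compression(st, proto, p, seed=rep, n_frames=2)
            disp = traj.chain[-1] - traj.chain[0]
            msds.extend(np.sum(disp**2, axis=1))
        t = 1.0
        assert np.mean(msds) == pytest.approx(6.0 * p.D_Teff * t, rel=0.10)

    def test_rouse_com_diffusion(self):
        # center-of-mass of a free Rouse chain diffuses at D/N
        N = 20
        p = NucleusParams(N=N, M_lam=0, N_C=0, N_L=0, K=140.0, K_ex=0.0, D_Teff=1.0)
        proto = constant_rate_protocol(0.0, 2.0)
        com_msds = []
        for rep in range(150):
            st = free_chain_state(N, rep, p)
            traj = run_compression(st, proto, p, seed=1000 + rep, n_frames=2)
            dc = traj.chain[-1].mean(axis=0) - traj.chain[0].mean(axis=0)
            com_msds.append(np.sum(dc**2))
        expected = 6.0 * p.D_Teff / N * 2.0
        assert np.mean(com_msds) == pytest.approx(expected, rel=0.10)

    def test_python_step_matches_fast_kernel(self, micro_state, micro_nucleus_params):
        p = micro_nucleus_params
        proto = constant_rate_protocol(0.2, 0.2)
        traj = run_compression(micro_state, proto, p, seed=5, n_frames=2)
        work = micro_state.copy()
        rng = stream_rng(5, "thermal")
        gap0 = 2 * np.max(np.abs(work.lamina[:, 2]))
        n_steps = int(round(0.2 / p.dt))
        for s in range(1, n_steps + 1):
            walls = plate_positions(gap0, proto, s * p.dt)
            work = step_nucleus(work, p, rng, walls=walls, in_place=True)
        assert np.allclose(work.chain, traj.chain[-1], atol=1e-12)
        assert np.allclose(work.lamina, traj.lamina[-1], atol=1e-12)

    def test_instability_detected_for_large_timestep(self, micro_state, micro_nucleus_params):
        p = replace(micro_nucleus_params, dt=0.02)
        proto = constant_rate_protocol(0.2, 1.0)
        with pytest.raises(InstabilityError):
            run_compression(micro_state, proto, p, seed=5, n_frames=2)

    def test_zero_rate_protocol_keeps_thermal_equilibrium_size(
        self, micro_state, micro_nucleus_params
    ):
        # without plates the floppy meshwork thermally crumples by ~10-15%
        # to its equilibrium size and then stays there: no collapse, no drift
        proto = constant_rate_protocol(0.0, 4.0)
        traj = run_compression(micro_state, proto, micro_nucleus_params, seed=8, n_frames=5)
        r = np.array([np.linalg.norm(traj.lamina[k], axis=1).mean() for k in range(5)])
        assert r.min() > 0.75 * r[0]  # bounded shrinkage, no collapse
        assert r[1:].max() < r[0]  # equilibrium size below the as-built sphere


class TestCompressionRun:
    def test_paired_identical_runs_are_bitwise_equal(self, micro_state, micro_nucleus_params):
        proto = constant_rate_protocol(0.3, 1.0)
        a = run_compression(micro_state, proto, micro_nucleus_params, seed=3, n_frames=3)
        b = run_compression(micro_state, proto, micro_nucleus_params, seed=3, n_frames=3)
        assert np.array_equal(a.chain, b.chain)
        assert np.array_equal(a.lamina, b.lamina)

    def test_wall_reaction_grows_with_strain(self, micro_compression):
        w = micro_compression.wall_force
        # time-averaged reaction at the end well above the early stage
        assert w[-1] > w[1]
        assert np.mean(w[-3:]) > np.mean(w[1:4])

    def test_chain_stays_inside_lamina(self, micro_compression):
        frac = max(
            chain_outside_fraction(micro_compression.chain[k], micro_compression.lamina[k])
            for k in range(micro_compression.n_frames)
        )
        assert frac <= 0.01

    def test_imposed_strain_reached(self, micro_compression):
        assert micro_compression.strains[-1] == pytest.approx(0.40, abs=1e-9)
        gap0 = micro_compression.manifest["gap0"]
        z0 = micro_compression.lamina[0][:, 2]
        z = micro_compression.lamina[-1][:, 2]
        # shell height tracks the plate gap; the soft one-sided walls leave
        # some elastic overhang beyond the nominal 60% gap
        assert np.ptp(z) < 0.85 * np.ptp(z0)


class TestMotors:
    def test_disabled_motors_exert_no_force(self, micro_state, micro_nucleus_params):
        F = motor_forces(micro_state, micro_nucleus_params)
        assert np.abs(F).max() == 0.0

    def test_contractile_pulls_neighbor_toward_motor(self):
        p = NucleusParams(
            N=2, M_lam=0, N_C=0, N_L=0,
            motors=MotorConfig(enabled=True, N_m=1, strength=2.0, force_range=0.5),
        )
        st = free_chain_state(2, 0, p)
        st.chain = np.array([[0.0, 0, 0], [0.3, 0, 0]])
        st.motor_indices = np.array([0])
        st.motor_clocks = np.array([1.0])
        F = motor_forces(st, p)
        assert F[1, 0] < 0  # pulled toward the motor at the origin
        assert np.allclose(F[0], 0)  # monopole: no reaction on the motor

    def test_extensile_pushes_away(self):
        p = NucleusParams(
            N=2, M_lam=0, N_C=0, N_L=0,
            motors=MotorConfig(enabled=True, N_m=1, strength=2.0,
                               force_range=0.5, extensile=True),
        )
        st = free_chain_state(2, 0, p)
        st.chain = np.array([[0.0, 0, 0], [0.3, 0, 0]])
        st.motor_indices = np.array([0])
        st.motor_clocks = np.array([1.0])
        assert motor_forces(st, p)[1, 0] > 0

    def test_turnover_fraction_matches_exponential_clocks(self):
        # advancing the clocks by tau relocates ~ 1 - 1/e of the motors
        N = 4000
        p = NucleusParams(N=N, M_lam=0, N_C=0, N_L=0,
                          motors=MotorConfig(enabled=True, N_m=1000, strength=1.0,
                                             force_range=0.1, tau_m=2.0))
        st = free_chain_state(N, 0, p)
        rng = np.random.default_rng(4)
        assign_motors(st, 1000, rng, p)
        before = st.motor_indices.copy()
        motor_turnover(st, p.motors.tau_m, rng, dt=p.motors.tau_m)
        frac = np.mean(st.motor_indices != before)
        assert frac == pytest.approx(1.0 - np.exp(-1.0), abs=0.04)
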