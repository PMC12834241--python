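"""Overdamped Brownian dynamics of the nucleus and plate compression.

Every monomer follows the Euler-Maruyama update

    r <- r + (dt / xi) (F_sp + F_ex + F_a + F_wall) + sqrt(2 D_Teff dt) eta

with eta standard normal per component.  Plate compression moves two
one-sided harmonic walls, initially tangent to the shell, symmetrically
toward each other; walls push only lamina monomers (the chromatin feels the
plates exclusively through the shell and its linkages).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import NucleusParams
from .state import NucleusState, stream_rng
from .forces import total_forces, _run_chunk_numba, _cross_sigma, _cross_kex
from ..protocols import PlateProtocol


class InstabilityError(RuntimeError):
    """Integration became unstable; advise a smaller dt."""


def _max_step(params: NucleusParams, amp: float) -> float:
    """Stability monitor: a per-step displacement beyond a few monomer
    diameters plus an 8-sigma thermal kick marks a force blow-up (the
    thermal kick alone has rms ``amp`` per component)."""
    return 5.0 * params.sigma + 8.0 * amp


def _initial_gap(state: NucleusState) -> float:
    """Plates start tangent to the undeformed shell (or to the chain extent
    for shell-free systems, where walls are inert anyway)."""
    ref = state.lamina if state.M else state.chain
    return 2.0 * float(np.max(np.abs(ref[:, 2]))) + (0.0 if state.M else 1.0)


def plate_positions(
    state_or_gap0, protocol: PlateProtocol, t: float
) -> tuple[float, float]:
    """(z_bot, z_top) of the plates at time ``t``.

    ``state_or_gap0`` is either a NucleusState (plates initialized tangent
    to the undeformed shell) or the initial gap as a float.
    """
    if isinstance(state_or_gap0, NucleusState):
        gap0 = _initial_gap(state_or_gap0)
    else:
        gap0 = float(state_or_gap0)
    gap = protocol.gap(t, gap0)
    half = 0.5 * gap
    return -half, half


def apply_plate_compression(
    state: NucleusState,
    protocol: PlateProtocol,
    t: float,
    params: NucleusParams | None = None,
    gap0: float | None = None,
) -> np.ndarray:
    """Wall forces at time ``t``: one-sided harmonic on lamina monomers
    beyond either plate, zero on chromatin.  Returns an (N+M, 3) array."""
    p = params or NucleusParams()
    z_bot, z_top = plate_positions(gap0 if gap0 is not None else state, protocol, t)
    F = np.zeros((state.N + state.M, 3))
    z = state.lamina[:, 2]
    over = z > z_top
    under = z < z_bot
    F[state.N :, 2][over] = -p.k_wall * (z[over] - z_top)
    F[state.N :, 2][under] = p.k_wall * (z_bot - z[under])
    return F


def step_nucleus(
    state: NucleusState,
    params: NucleusParams,
    rng: np.random.Generator,
    walls: tuple[float, float] | None = None,
    in_place: bool = False,
) -> NucleusState:
    """One Euler-Maruyama step (reference python path).

    The fast chunked integrator in :func:`run_compression` reproduces this
    step bit-for-bit given the same noise (asserted in the test suite).
    """
    out = state if in_place else state.copy()
    pos = out.positions
    F = total_forces(out, params, walls=walls)
    disp = (params.dt / params.xi) * F
    amp = np.sqrt(2.0 * params.D_Teff * params.dt)
    if params.D_Teff > 0:
        disp = disp + amp * rng.standard_normal(pos.shape)
    if np.max(np.abs(disp)) > _max_step(params, amp):
        raise InstabilityError(
            "per-step displacement far beyond the monomer scale; reduce dt"
        )
    out.set_positions(pos + disp)
    if params.motors.enabled and out.motor_indices is not None:
        from .motors import motor_turnover

        motor_turnover(out, params.motors.tau_m, rng, params.dt)
    return out


@dataclass
class NucleusTrajectory:
    """Recorded frames of a compression run."""

    times: np.ndarray
    strains: np.ndarray  # imposed plate strain per frame
    chain: np.ndarray  # (F, N, 3)
    lamina: np.ndarray  # (F, M, 3)
    wall_force: np.ndarray  # mean |wall reaction| per recorded interval
    state0: NucleusState
    manifest: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.times.size

    def frame_at_strain(self, strain: float) -> int:
        """Index of the first frame at or beyond ``strain``."""
        idx = np.searchsorted(self.strains, strain - 1e-12)
        return int(min(idx, self.n_frames - 1))


def run_compression(
    state: NucleusState,
    protocol: PlateProtocol,
    params: NucleusParams,
    seed: int,
    n_frames: int = 21,
    duration: float | None = None,
    chunk: int = 250,
) -> NucleusTrajectory:
    """Integrate the nucleus under the plate protocol (times in sim units).

    Thermal noise comes from the named ``thermal`` stream of ``seed``, so
    paired runs differing only in their crosslink set consume identical
    noise.  Frames (chain + lamina positions, achieved strain, mean wall
    reaction force) are recorded at ``n_frames`` evenly spaced times.
    """
    if params.motors.enabled:
        # motors need per-step python bookkeeping; fixture scale only
        return _run_compression_python(state, protocol, params, seed, n_frames, duration)
    duration = protocol.duration if duration is None else duration
    n_steps = max(1, int(round(duration / params.dt)))
    frame_steps = np.unique(np.linspace(0, n_steps, n_frames).astype(int))
    rng = stream_rng(seed, "thermal")

    work = state.copy()
    pos = np.ascontiguousarray(work.positions)
    bonds, rest = work.all_bonds()
    gap0 = _initial_gap(work)
    amp = np.sqrt(2.0 * params.D_Teff * params.dt)

    times, strains, chains, laminas, wallf = [], [], [], [], []

    def record(step, wmean):
        t = step * params.dt
        times.append(t)
        strains.append(protocol.strain(t))
        chains.append(pos[: work.N].copy())
        laminas.append(pos[work.N :].copy())
        wallf.append(wmean)

    record(0, 0.0)
    step = 0
    while step < n_steps:
        n_sub = min(chunk, n_steps - step)
        # stop the chunk at the next frame boundary
        nxt = frame_steps[np.searchsorted(frame_steps, step, side="right"):]
        if nxt.size:
            n_sub = min(n_sub, int(nxt[0]) - step)
        noise = amp * rng.standard_normal((n_sub, pos.shape[0], 3))
        tgrid = (step + 1 + np.arange(n_sub)) * params.dt
        half = np.array([0.5 * protocol.gap(t, gap0) for t in tgrid])
        wall_fsum = np.empty(n_sub)
        done, unstable = _run_chunk_numba(
            pos, work.N, bonds, rest, params.K, params.sigma, params.K_ex,
            _cross_sigma(params), _cross_kex(params), params.dt / params.xi,
            noise, -half, half, params.k_wall, _max_step(params, amp), wall_fsum,
        )
        if unstable:
            raise InstabilityError(
                f"instability at step {step + done}: displacement > sigma; reduce dt"
            )
        step += n_sub
        if step in frame_steps:
            record(step, float(np.mean(wall_fsum)))
    work.set_positions(pos)
    traj = NucleusTrajectory(
        times=np.asarray(times),
        strains=np.asarray(strains),
        chain=np.asarray(chains),
        lamina=np.asarray(laminas),
        wall_force=np.asarray(wallf),
        state0=state.copy(),
        manifest={
            "seed": int(seed),
            "N": work.N,
            "M": work.M,
            "N_C": int(work.crosslink_bonds.shape[0]),
            "N_L": int(work.linkage_bonds.shape[0]),
            "dt": params.dt,
            "duration": duration,
            "total_strain": protocol.total_strain,
            "gap0": gap0,
        },
    )
    return traj


def _mean_wall_reaction(pos, n_chain, z_bot, z_top, k_wall) -> float:
    z = pos[n_chain:, 2]
    f = k_wall * (np.maximum(z - z_top, 0.0) + np.maximum(z_bot - z, 0.0))
    return float(np.sum(f))


def _run_compression_python(state, protocol, params, seed, n_frames, duration):
    """Slow reference path (used when motors are enabled)."""
    duration = protocol.duration if duration is None else duration
    n_steps = max(1, int(round(duration / params.dt)))
    frame_steps = np.unique(np.linspace(0, n_steps, n_frames).astype(int))
    rng = stream_rng(seed, "thermal")
    work = state.copy()
    gap0 = _initial_gap(work)
    times, strains, chains, laminas, wallf = [0.0], [0.0], [work.chain.copy()], [
        work.lamina.copy()
    ], [0.0]
    for step in range(1, n_steps + 1):
        t = step * params.dt
        walls = plate_positions(gap0, protocol, t)
        work = step_nucleus(work, params, rng, walls=walls, in_place=True)
        if step in frame_steps:
            times.append(t)
            strains.append(protocol.strain(t))
            chains.append(work.chain.copy())
            laminas.append(work.lamina.copy())
            wallf.append(
                _mean_wall_reaction(work.positions, work.N, walls[0], walls[1], params.k_wall)
            )
    return NucleusTrajectory(
        times=np.asarray(times),
        strains=np.asarray(strains),
        chain=np.asarray(chains),
        lamina=np.asarray(laminas),
        wall_force=np.asarray(wallf),
        state0=state.copy(),
        manifest={"seed": int(seed), "motors": True},
    )
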