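"""Monopole motors: active chain monomers acting non-reciprocally on their
neighbors.  Contractile motors pull monomers within range toward the motor;
extensile motors push them away.  The motor itself feels no reaction force
(a force monopole).  Motors relocate with exponential clocks of mean tau_m.

Off by default; the compression studies run without activity.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .params import NucleusParams


def assign_motors(state, N_m: int, rng: np.random.Generator, params: NucleusParams):
    """Pick ``N_m`` distinct chain monomers as motors with fresh clocks."""
    if N_m > state.N:
        raise ValueError("more motors than chain monomers")
    idx = rng.choice(state.N, size=N_m, replace=False)
    state.motor_indices = np.sort(idx).astype(np.int64)
    state.motor_clocks = rng.exponential(params.motors.tau_m, size=N_m)
    return state


def motor_forces(state, params: NucleusParams) -> np.ndarray:
    """(N, 3) active forces on chain monomers from all motors."""
    cfg = params.motors
    if not cfg.enabled or state.motor_indices is None or state.motor_indices.size == 0:
        return np.zeros((state.N, 3))
    if cfg.force_range <= 0:
        raise ValueError("motor force range must be positive")
    F = np.zeros((state.N, 3))
    tree = cKDTree(state.chain)
    sign = +1.0 if cfg.extensile else -1.0  # -1: pull toward the motor
    for m in state.motor_indices:
        rm = state.chain[m]
        for j in tree.query_ball_point(rm, cfg.force_range):
            if j == m:
                continue
            d = state.chain[j] - rm
            L = np.linalg.norm(d)
            if L < 1e-12:
                continue
            F[j] += sign * cfg.strength * d / L
    return F


def motor_turnover(state, tau_m: float, rng: np.random.Generator, dt: float):
    """Advance motor clocks by ``dt``; expired motors jump to a uniformly
    chosen non-motor chain monomer and restart their exponential clock."""
    if state.motor_indices is None or state.motor_indices.size == 0:
        return state
    state.motor_clocks = state.motor_clocks - dt
    expired = np.nonzero(state.motor_clocks <= 0)[0]
    if expired.size:
        occupied = set(int(i) for i in state.motor_indices)
        free = np.array([i for i in range(state.N) if i not in occupied])
        dest = rng.choice(free, size=expired.size, replace=False)
        for slot, new_idx in zip(expired, dest):
            state.motor_indices[slot] = new_idx
            state.motor_clocks[slot] = rng.exponential(tau_m)
    return state
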