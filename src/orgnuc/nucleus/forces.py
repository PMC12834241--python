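"""Force field of the nucleus model.

Interactions: Hookean springs (chain, crosslink, lamina-shell, linkage, all
stiffness K, per-bond rest lengths), a harmonic soft-core repulsion

    U_ex = (K_ex / 2) (sigma_ij - r)^2   for r < sigma_ij, else 0

between monomer pairs, and one-sided harmonic walls acting on lamina
monomers only.  Within the chain and within the lamina sigma_ij is the sum
of monomer radii (2 r_c).  Chain-lamina pairs use a wider range
``chain_lamina_sigma_factor * 2 r_c`` (default 2x): the lamina is a
10-30 nm filamentous sheet, not a string of point beads, and at the model's
thermal energy the bare bead-bead barrier (~K_ex (2 r_c)^2 ~ 1.4 kT) would
let the chain diffuse straight through the meshwork.  The widened shell
interaction makes the lamina an effective surface barrier while leaving
nuclear dimensions untouched.

The inner kernels are numba-compiled with a linked-cell neighbor list; the
pure-numpy energy routine at the bottom is deliberately independent
(brute-force pairs) so force/energy consistency can be cross-checked.
"""

from __future__ import annotations

import logging

import numpy as np
from numba import njit

log = logging.getLogger(__name__)

_FALLBACK_DIR = np.array([1.0, 0.0, 0.0])


def soft_core_force(r_i, r_j, sigma_ij: float, K_ex: float) -> np.ndarray:
    """Soft-core repulsive force on monomer i from monomer j.

    ``K_ex * (sigma_ij - r) * rhat`` for r < sigma_ij, zero otherwise;
    antisymmetric under i <-> j.  Coincident monomers get a deterministic
    fallback direction with the maximal magnitude ``K_ex * sigma_ij``.
    """
    if sigma_ij <= 0:
        raise ValueError("sigma_ij must be positive")
    d = np.asarray(r_i, dtype=float) - np.asarray(r_j, dtype=float)
    r = float(np.linalg.norm(d))
    if r < 1e-12:
        log.warning("coincident monomers: applying fallback repulsion direction")
        return K_ex * sigma_ij * _FALLBACK_DIR
    if r >= sigma_ij:
        return np.zeros(3)
    return K_ex * (sigma_ij - r) * d / r


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _spring_numba(pos, bonds, rest, K, F):
    """Accumulate spring forces into F; returns potential energy."""
    U = 0.0
    for k in range(bonds.shape[0]):
        i, j = bonds[k, 0], bonds[k, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        L = np.sqrt(dx * dx + dy * dy + dz * dz)
        if L < 1e-12:
            continue
        f = K * (L - rest[k]) / L
        F[i, 0] += f * dx
        F[i, 1] += f * dy
        F[i, 2] += f * dz
        F[j, 0] -= f * dx
        F[j, 1] -= f * dy
        F[j, 2] -= f * dz
        U += 0.5 * K * (L - rest[k]) ** 2
    return U


@njit(cache=True)
def _grid_dims(pos, cutoff, cap):
    lox = hix = pos[0, 0]
    loy = hiy = pos[0, 1]
    loz = hiz = pos[0, 2]
    for i in range(pos.shape[0]):
        if pos[i, 0] < lox:
            lox = pos[i, 0]
        elif pos[i, 0] > hix:
            hix = pos[i, 0]
        if pos[i, 1] < loy:
            loy = pos[i, 1]
        elif pos[i, 1] > hiy:
            hiy = pos[i, 1]
        if pos[i, 2] < loz:
            loz = pos[i, 2]
        elif pos[i, 2] > hiz:
            hiz = pos[i, 2]
    # cubic cells of width >= cutoff, grown until the grid fits the buffer
    w = cutoff + 1e-12
    nx = int((hix - lox) / w) + 1
    ny = int((hiy - loy) / w) + 1
    nz = int((hiz - loz) / w) + 1
    while nx * ny * nz + 1 > cap:
        w *= 1.26
        nx = int((hix - lox) / w) + 1
        ny = int((hiy - loy) / w) + 1
        nz = int((hiz - loz) / w) + 1
    return lox, loy, loz, 1.0 / w, nx, ny, nz


@njit(cache=True)
def _sort_cells(pos, i0, i1, lox, loy, loz, inv_w, nx, ny, nz, start, order, cell):
    """Counting-sort points [i0, i1) into contiguous per-bin index ranges.

    After the call, bin b holds points order[start[b]:start[b+1]].
    """
    nbins = nx * ny * nz
    for bb in range(nbins + 1):
        start[bb] = 0
    for i in range(i0, i1):
        cx = int((pos[i, 0] - lox) * inv_w)
        cy = int((pos[i, 1] - loy) * inv_w)
        cz = int((pos[i, 2] - loz) * inv_w)
        if cx >= nx:
            cx = nx - 1
        if cy >= ny:
            cy = ny - 1
        if cz >= nz:
            cz = nz - 1
        bb = (cx * ny + cy) * nz + cz
        cell[i] = bb
        start[bb + 1] += 1
    for bb in range(nbins):
        start[bb + 1] += start[bb]
    for i in range(i0, i1):
        bb = cell[i]
        order[start[bb]] = i
        start[bb] += 1
    # undo the in-place shift
    for bb in range(nbins, 0, -1):
        start[bb] = start[bb - 1]
    start[0] = 0


@njit(cache=True)
def _pair_kick(pos, i, j, sig, s2, k_ex, F):
    dx = pos[i, 0] - pos[j, 0]
    dy = pos[i, 1] - pos[j, 1]
    dz = pos[i, 2] - pos[j, 2]
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= s2:
        return 0.0
    r = np.sqrt(r2)
    if r < 1e-12:
        F[i, 0] += k_ex * sig
        F[j, 0] -= k_ex * sig
        return 0.5 * k_ex * s2
    f = k_ex * (sig - r) / r
    F[i, 0] += f * dx
    F[i, 1] += f * dy
    F[i, 2] += f * dz
    F[j, 0] -= f * dx
    F[j, 1] -= f * dy
    F[j, 2] -= f * dz
    return 0.5 * k_ex * (sig - r) ** 2


@njit(cache=True)
def _soft_core_impl(pos, n_chain, sigma, k_ex, sigma_cross, k_ex_cross, F,
                    start, order, cell):
    """Two-pass linked-cell soft core.

    Pass 1: same-species pairs (chain-chain, lamina-lamina) at range
    ``sigma``, half-stencil over sorted bins.  Pass 2: chain-lamina pairs at
    range ``sigma_cross`` with stiffness ``k_ex_cross`` (0 disables the
    pass); the lamina alone is binned and chain monomers probe the grid.
    Returns the potential energy.
    """
    n = pos.shape[0]
    U = 0.0
    if n == 0:
        return U
    cap = start.shape[0]
    if k_ex > 0.0 and sigma > 0.0:
        lox, loy, loz, inv_w, nx, ny, nz = _grid_dims(pos, sigma, cap)
        _sort_cells(pos, 0, n, lox, loy, loz, inv_w, nx, ny, nz, start, order, cell)
        s2 = sigma * sigma
        nyz = ny * nz
        for bb in range(nx * ny * nz):
            a0 = start[bb]
            a1 = start[bb + 1]
            if a0 == a1:
                continue
            cz0 = bb % nz
            cy0 = (bb // nz) % ny
            cx0 = bb // nyz
            # pairs within the bin
            for u in range(a0, a1):
                i = order[u]
                ic = i < n_chain
                for v in range(u + 1, a1):
                    j = order[v]
                    if ic == (j < n_chain):
                        U += _pair_kick(pos, i, j, sigma, s2, k_ex, F)
            # forward half-stencil of 13 neighbor bins
            for t in range(13):
                if t == 0:
                    dxc, dyc, dzc = 0, 0, 1
                elif t == 1:
                    dxc, dyc, dzc = 0, 1, -1
                elif t == 2:
                    dxc, dyc, dzc = 0, 1, 0
                elif t == 3:
                    dxc, dyc, dzc = 0, 1, 1
                elif t == 4:
                    dxc, dyc, dzc = 1, -1, -1
                elif t == 5:
                    dxc, dyc, dzc = 1, -1, 0
                elif t == 6:
                    dxc, dyc, dzc = 1, -1, 1
                elif t == 7:
                    dxc, dyc, dzc = 1, 0, -1
                elif t == 8:
                    dxc, dyc, dzc = 1, 0, 0
                elif t == 9:
                    dxc, dyc, dzc = 1, 0, 1
                elif t == 10:
                    dxc, dyc, dzc = 1, 1, -1
                elif t == 11:
                    dxc, dyc, dzc = 1, 1, 0
                else:
                    dxc, dyc, dzc = 1, 1, 1
                cx = cx0 + dxc
                cy = cy0 + dyc
                cz = cz0 + dzc
                if cx < 0 or cx >= nx or cy < 0 or cy >= ny or cz < 0 or cz >= nz:
                    continue
                b2 = (cx * ny + cy) * nz + cz
                b0 = start[b2]
                b1 = start[b2 + 1]
                for u in range(a0, a1):
                    i = order[u]
                    ic = i < n_chain
                    for v in range(b0, b1):
                        j = order[v]
                        if ic == (j < n_chain):
                            U += _pair_kick(pos, i, j, sigma, s2, k_ex, F)
    if k_ex_cross > 0.0 and sigma_cross > 0.0 and 0 < n_chain < n:
        lox, loy, loz, inv_w, nx, ny, nz = _grid_dims(pos, sigma_cross, cap)
        _sort_cells(pos, n_chain, n, lox, loy, loz, inv_w, nx, ny, nz, start,
                    order, cell)
        sc2 = sigma_cross * sigma_cross
        for i in range(n_chain):
            cx0 = int((pos[i, 0] - lox) * inv_w)
            cy0 = int((pos[i, 1] - loy) * inv_w)
            cz0 = int((pos[i, 2] - loz) * inv_w)
            for cx in range(max(0, cx0 - 1), min(nx, cx0 + 2)):
                for cy in range(max(0, cy0 - 1), min(ny, cy0 + 2)):
                    for cz in range(max(0, cz0 - 1), min(nz, cz0 + 2)):
                        b2 = (cx * ny + cy) * nz + cz
                        for v in range(start[b2], start[b2 + 1]):
                            U += _pair_kick(pos, i, order[v], sigma_cross, sc2,
                                            k_ex_cross, F)
    return U


@njit(cache=True)
def _soft_core_numba(pos, sigma, k_ex, F, sigma_cross=0.0, n_chain=-1,
                     k_ex_cross=0.0):
    """Convenience wrapper allocating the linked-cell work arrays.

    With ``n_chain < 0`` every pair interacts at ``sigma`` (single-species
    view); otherwise same-species pairs use ``sigma`` and chain-lamina
    pairs ``sigma_cross`` / ``k_ex_cross``.
    """
    n = pos.shape[0]
    start = np.empty(16 * n + 64, dtype=np.int64)
    order = np.empty(n, dtype=np.int64)
    cell = np.empty(n, dtype=np.int64)
    if n_chain < 0:
        return _soft_core_impl(pos, n, sigma, k_ex, 0.0, 0.0, F, start, order, cell)
    return _soft_core_impl(pos, n_chain, sigma, k_ex, sigma_cross, k_ex_cross,
                           F, start, order, cell)


@njit(cache=True)
def _wall_numba(pos, n_chain, z_bot, z_top, k_wall, F):
    """One-sided harmonic walls on lamina monomers (indices >= n_chain)."""
    U = 0.0
    for i in range(n_chain, pos.shape[0]):
        z = pos[i, 2]
        if z > z_top:
            F[i, 2] -= k_wall * (z - z_top)
            U += 0.5 * k_wall * (z - z_top) ** 2
        elif z < z_bot:
            F[i, 2] += k_wall * (z_bot - z)
            U += 0.5 * k_wall * (z_bot - z) ** 2
    return U


@njit(cache=True)
def _run_chunk_numba(
    pos, n_chain, bonds, rest, K, sigma, k_ex, sigma_cross, k_ex_cross,
    dt_over_xi, noise, z_bot, z_top, k_wall, max_disp, wall_fsum,
):
    """Euler-Maruyama steps over one noise chunk; returns (steps done,
    unstable flag).  ``wall_fsum[s]`` records the summed |wall force|."""
    nsteps = noise.shape[0]
    n = pos.shape[0]
    F = np.zeros((n, 3))
    start = np.empty(16 * n + 64, dtype=np.int64)
    order = np.empty(n, dtype=np.int64)
    cell = np.empty(n, dtype=np.int64)
    for s in range(nsteps):
        for i in range(n):
            F[i, 0] = 0.0
            F[i, 1] = 0.0
            F[i, 2] = 0.0
        _spring_numba(pos, bonds, rest, K, F)
        _soft_core_impl(pos, n_chain, sigma, k_ex, sigma_cross, k_ex_cross,
                        F, start, order, cell)
        wsum = 0.0
        for i in range(n_chain, n):
            z = pos[i, 2]
            if z > z_top[s]:
                fz = -k_wall * (z - z_top[s])
                F[i, 2] += fz
                wsum -= fz
            elif z < z_bot[s]:
                fz = k_wall * (z_bot[s] - z)
                F[i, 2] += fz
                wsum += fz
        wall_fsum[s] = wsum
        for i in range(n):
            for d in range(3):
                dr = dt_over_xi * F[i, d] + noise[s, i, d]
                if dr > max_disp or dr < -max_disp:
                    return s, True
                pos[i, d] += dr
    return nsteps, False


# ---------------------------------------------------------------------------
# assembled force field (python surface)
# ---------------------------------------------------------------------------

def _cross_sigma(params) -> float:
    if not params.chain_lamina_excluded:
        return 0.0
    return params.chain_lamina_sigma_factor * params.sigma


def _cross_kex(params) -> float:
    if not params.chain_lamina_excluded:
        return 0.0
    return params.chain_lamina_kex_factor * params.K_ex


def total_forces(state, params, walls=None, include_motors: bool = True):
    """All internal forces (springs + excluded volume [+ motors]) plus wall
    forces if ``walls=(z_bot, z_top)`` is given.  Returns an (n, 3) array in
    the state's global index order (chain first, then lamina)."""
    pos = state.positions
    F = np.zeros_like(pos)
    bonds, rest = state.all_bonds()
    _spring_numba(pos, bonds, rest, params.K, F)
    _soft_core_numba(pos, params.sigma, params.K_ex, F, _cross_sigma(params),
                     state.N, _cross_kex(params))
    if walls is not None:
        _wall_numba(pos, state.N, walls[0], walls[1], params.k_wall, F)
    if include_motors and params.motors.enabled and state.motor_indices is not None:
        from .motors import motor_forces

        F[: state.N] += motor_forces(state, params)
    if not np.all(np.isfinite(F)):
        raise FloatingPointError("non-finite force in nucleus model")
    return F


def potential_energy(state, params, walls=None) -> float:
    """Brute-force potential energy (independent of the cell-list kernels).

    Used as the finite-difference reference for force consistency; O(n^2)
    in the excluded-volume term, so fixture scale only.
    """
    pos = state.positions
    bonds, rest = state.all_bonds()
    d = pos[bonds[:, 1]] - pos[bonds[:, 0]]
    L = np.linalg.norm(d, axis=1)
    U = 0.5 * params.K * np.sum((L - rest) ** 2)
    diff = pos[:, None, :] - pos[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    iu = np.triu_indices(pos.shape[0], k=1)
    rr = r[iu]
    cross = (iu[0] < state.N) != (iu[1] < state.N)
    sig = np.where(cross, _cross_sigma(params), params.sigma)
    kex = np.where(cross, _cross_kex(params), params.K_ex)
    ov = np.maximum(sig - rr, 0.0)
    U += 0.5 * np.sum(kex * ov**2)
    if walls is not None:
        z = pos[state.N :, 2]
        U += 0.5 * params.k_wall * np.sum(np.maximum(z - walls[1], 0.0) ** 2)
        U += 0.5 * params.k_wall * np.sum(np.maximum(walls[0] - z, 0.0) ** 2)
    return float(U)


def chain_outside_fraction(chain: np.ndarray, lamina: np.ndarray) -> float:
    """Fraction of chain monomers outside the lamina surface.

    The surface is taken as the convex hull of the lamina beads (the
    compressed shell stays near-convex; wrinkles are small against the
    monomer scale).
    """
    from scipy.spatial import Delaunay

    return float(np.mean(Delaunay(lamina).find_simplex(chain) < 0))
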