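"""Construction of the nucleus: lamina shell, chromatin chain, crosslinks,
linkages.  All builders are deterministic per seed."""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .params import NucleusParams


class BuildError(RuntimeError):
    pass


def _fibonacci_sphere(m: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    k = np.arange(m, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / m
    theta = 2.0 * np.pi * k / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _relax_on_sphere(pts: np.ndarray, radius: float, d: float, n_sweeps: int = 20):
    """Short repulsive relaxation constrained to the sphere surface."""
    for _ in range(n_sweeps):
        tree = cKDTree(pts)
        pairs = tree.query_pairs(d, output_type="ndarray")
        if pairs.size == 0:
            break
        disp = np.zeros_like(pts)
        dv = pts[pairs[:, 0]] - pts[pairs[:, 1]]
        L = np.linalg.norm(dv, axis=1)
        L = np.maximum(L, 1e-12)
        push = 0.25 * (d - L)[:, None] * dv / L[:, None]
        np.add.at(disp, pairs[:, 0], push)
        np.add.at(disp, pairs[:, 1], -push)
        pts = pts + disp
        pts *= radius / np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def build_lamina_shell(
    M_lam: int,
    radius: float | None = None,
    z_target: float = 4.5,
    seed: int = 0,
    params: NucleusParams | None = None,
    tol: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-uniform spherical shell of ``M_lam`` monomers bonded by springs.

    Bonds join monomers closer than a distance cutoff tuned by bisection so
    the mean coordination number falls within ``z_target +/- tol`` (the
    imaged lamina meshwork has z ~ 4.5); the bond graph must be connected.
    Returns ``(positions, bonds)``; spring rest lengths are the as-built
    separations, so a freshly built shell is force-free.
    """
    if M_lam < 12:
        raise BuildError("need at least 12 monomers to form a shell")
    p = params or NucleusParams()
    if radius is None:
        d = p.shell_spacing_factor * p.sigma
        radius = d * np.sqrt(np.sqrt(3.0) * M_lam / (8.0 * np.pi))
    rng = np.random.default_rng(seed)
    spacing = np.sqrt(4.0 * np.pi * radius**2 / M_lam)
    pts = _fibonacci_sphere(M_lam) * radius
    pts += 0.05 * spacing * rng.standard_normal(pts.shape)
    pts *= radius / np.linalg.norm(pts, axis=1, keepdims=True)
    pts = _relax_on_sphere(pts, radius, 0.95 * spacing)

    tree = cKDTree(pts)

    def mean_degree(cutoff: float) -> tuple[float, np.ndarray]:
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        return 2.0 * pairs.shape[0] / M_lam, pairs

    lo, hi = 0.5 * spacing, 3.0 * spacing
    zlo, _ = mean_degree(lo)
    zhi, _ = mean_degree(hi)
    if not (zlo < z_target < zhi):
        raise BuildError(
            f"cannot bracket target coordination {z_target}: [{zlo:.2f}, {zhi:.2f}]"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        z, pairs = mean_degree(mid)
        if abs(z - z_target) <= tol:
            break
        if z < z_target:
            lo = mid
        else:
            hi = mid
    else:
        raise BuildError("coordination bisection failed to converge")

    adj = csr_matrix(
        (np.ones(pairs.shape[0]), (pairs[:, 0], pairs[:, 1])), shape=(M_lam, M_lam)
    )
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp != 1:
        raise BuildError(f"lamina bond graph has {n_comp} components")
    bonds = np.sort(pairs, axis=1)
    order = np.lexsort((bonds[:, 1], bonds[:, 0]))
    return pts, bonds[order]


def init_chromatin(
    N: int,
    shell_positions: np.ndarray,
    seed: int = 0,
    params: NucleusParams | None = None,
    relax_steps: int = 400,
) -> np.ndarray:
    """Confined random-walk chain inside the shell, overlap-relaxed.

    A random walk with step 2*r_c is reflected back into the sphere the
    shell's repulsion zone leaves free; residual monomer overlaps are then
    reduced by a short soft-core-only descent (chain connectivity is
    restored by setting bond rest lengths to the as-built separations
    afterwards).
    """
    p = params or NucleusParams()
    R = float(np.linalg.norm(shell_positions, axis=1).mean())
    # stay clear of the shell's repulsion zone (the chain-lamina soft core
    # reaches further than the bare monomer contact)
    from .forces import _cross_sigma

    r_max = R - max(p.sigma, _cross_sigma(p))
    if r_max <= p.sigma:
        raise BuildError("shell too small to hold the chain")
    rng = np.random.default_rng(seed)
    step = p.sigma
    pos = np.zeros((N, 3))
    pos[0] = rng.uniform(-0.3, 0.3, 3) * r_max
    for i in range(1, N):
        d = rng.standard_normal(3)
        nxt = pos[i - 1] + step * d / np.linalg.norm(d)
        r = np.linalg.norm(nxt)
        if r > r_max:  # reflect radially back inside
            nxt *= (2.0 * r_max - r) / r
        pos[i] = nxt

    # soft-core-only descent to reduce overlaps
    from .forces import _soft_core_numba

    eta = 0.5 / max(p.K_ex, 1e-12)
    for _ in range(relax_steps):
        F = np.zeros_like(pos)
        U = _soft_core_numba(pos, p.sigma, p.K_ex, F)
        if U < 1e-12:
            break
        pos += eta * F
        r = np.linalg.norm(pos, axis=1)
        outside = r > r_max
        pos[outside] *= (r_max / r[outside])[:, None]
    return pos


def place_crosslinks(
    chain_positions: np.ndarray,
    N_C: int,
    seed: int = 0,
    mode: str = "proximal",
    capture_radius: float | None = None,
    params: NucleusParams | None = None,
) -> np.ndarray:
    """``N_C`` distinct crosslinked monomer pairs with chain separation >= 2.

    Crosslinks are springs with the chain stiffness; adjacent pairs (i, i+1)
    are excluded since those are already chain bonds.  In the default
    ``"proximal"`` mode pairs are sampled uniformly among pairs currently
    within ``capture_radius`` (default two monomer diameters, 4 r_c):
    molecular crosslinkers bridge spatially nearby loci, which makes the
    crosslinked chain a local gel whose rigidity responds cooperatively to
    crosslink removal.  ``"uniform"`` samples uniformly among all
    non-adjacent pairs regardless of distance.
    """
    N = chain_positions.shape[0]
    if N_C < 0:
        raise ValueError("N_C must be non-negative")
    rng = np.random.default_rng(seed)
    if mode == "proximal":
        p = params or NucleusParams()
        r_cap = 2.0 * p.sigma if capture_radius is None else capture_radius
        pairs = cKDTree(chain_positions).query_pairs(r_cap, output_type="ndarray")
        if pairs.size:
            pairs = pairs[np.abs(pairs[:, 0] - pairs[:, 1]) >= 2]
        if pairs.shape[0] < N_C:
            raise BuildError(
                f"only {pairs.shape[0]} candidate pairs within capture radius "
                f"{r_cap:g} for N_C={N_C}; enlarge the radius or the chain"
            )
        take = rng.choice(pairs.shape[0], size=N_C, replace=False)
        out = np.sort(pairs[take], axis=1).astype(np.int64)
        return out[np.lexsort((out[:, 1], out[:, 0]))]
    if mode != "uniform":
        raise ValueError(f"unknown crosslink mode {mode!r}")
    n_avail = N * (N - 1) // 2 - (N - 1)
    if N_C > n_avail:
        raise BuildError(f"N_C={N_C} exceeds the {n_avail} non-adjacent pairs")
    chosen: set[tuple[int, int]] = set()
    out = np.empty((N_C, 2), dtype=np.int64)
    k = 0
    while k < N_C:
        draw = rng.integers(0, N, size=(max(64, 2 * (N_C - k)), 2))
        for i, j in draw:
            if abs(int(i) - int(j)) < 2:
                continue
            pair = (min(int(i), int(j)), max(int(i), int(j)))
            if pair in chosen:
                continue
            chosen.add(pair)
            out[k] = pair
            k += 1
            if k == N_C:
                break
    return out


def remove_crosslinks(crosslinks: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Remove ``k`` crosslinks uniformly at random; nested across ``k``.

    A single seed-determined permutation orders the crosslinks; the first
    ``k`` are dropped.  For a fixed seed the removal sets are therefore
    nested (k=20 removes a superset of k=10), which keeps paired
    reference/perturbed comparisons monotone in the perturbation size.
    """
    if k < 0:
        raise ValueError("cannot remove a negative number of crosslinks")
    n = crosslinks.shape[0]
    if k > n:
        raise ValueError(f"cannot remove {k} of {n} crosslinks")
    perm = np.random.default_rng(seed).permutation(n)
    keep = np.sort(perm[k:])
    return crosslinks[keep]


def crosslink_change_percent(k_removed: int, n_total: int) -> float:
    """Relative perturbation size in percent (10 of 2500 -> 0.4%)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * k_removed / n_total


def place_linkages(
    chain_positions: np.ndarray,
    shell_positions: np.ndarray,
    N_L: int,
    seed: int = 0,
) -> np.ndarray:
    """``N_L`` permanent shell-chain springs (LAD analogs).

    Random distinct shell monomers are each tied to their nearest
    not-yet-linked chain monomer.  Returns (shell_idx, chain_idx) pairs;
    each chain monomer is used at most once.
    """
    N, M = chain_positions.shape[0], shell_positions.shape[0]
    if N_L > min(N, M):
        raise BuildError("N_L exceeds available monomers")
    rng = np.random.default_rng(seed)
    shell_idx = rng.choice(M, size=N_L, replace=False)
    tree = cKDTree(chain_positions)
    used: set[int] = set()
    out = np.empty((N_L, 2), dtype=np.int64)
    for row, s in enumerate(shell_idx):
        k = 1
        while True:
            _, nn = tree.query(shell_positions[s], k=k)
            cand = np.atleast_1d(nn)
            free = [int(c) for c in cand if int(c) not in used]
            if free:
                c = free[0]
                break
            k = min(2 * k, N)
        used.add(c)
        out[row] = (s, c)
    return out
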