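"""Nucleus state container and the seeded assembly of a full nucleus."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import NucleusParams
from .build import (
    build_lamina_shell,
    init_chromatin,
    place_crosslinks,
    place_linkages,
)

# fixed stream codes so paired runs can share individual streams exactly
STREAMS = {"build": 11, "thermal": 23, "removal": 37, "motors": 53}


def stream_rng(root_seed: int, name: str) -> np.random.Generator:
    """Named, independent random stream derived from one root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(root_seed), STREAMS[name]]))


@dataclass
class NucleusState:
    """Positions and bond sets of one nucleus.

    Global index order is chain monomers [0, N) then lamina [N, N+M); all
    bond arrays use global indices except ``linkage_bonds`` whose rows are
    (shell index, chain index) as built (converted on the fly).
    """

    chain: np.ndarray
    lamina: np.ndarray
    chain_bonds: np.ndarray
    crosslink_bonds: np.ndarray
    lamina_bonds: np.ndarray
    linkage_bonds: np.ndarray  # (shell_idx, chain_idx)
    chain_rest: np.ndarray
    crosslink_rest: np.ndarray
    lamina_rest: np.ndarray
    linkage_rest: np.ndarray
    motor_indices: np.ndarray | None = None
    motor_clocks: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return self.chain.shape[0]

    @property
    def M(self) -> int:
        return self.lamina.shape[0]

    @property
    def positions(self) -> np.ndarray:
        return np.vstack([self.chain, self.lamina])

    def set_positions(self, pos: np.ndarray) -> None:
        self.chain = pos[: self.N].copy()
        self.lamina = pos[self.N :].copy()

    def all_bonds(self) -> tuple[np.ndarray, np.ndarray]:
        """(bonds, rest) in global indices, all four bond types stacked."""
        N = self.N
        link_global = np.column_stack(
            [self.linkage_bonds[:, 0] + N, self.linkage_bonds[:, 1]]
        ) if self.linkage_bonds.size else np.empty((0, 2), dtype=np.int64)
        bonds = np.vstack(
            [
                self.chain_bonds,
                self.crosslink_bonds.reshape(-1, 2),
                self.lamina_bonds + N,
                link_global,
            ]
        ).astype(np.int64)
        rest = np.concatenate(
            [self.chain_rest, self.crosslink_rest, self.lamina_rest, self.linkage_rest]
        )
        return bonds, rest

    def bond_table(self) -> list[tuple[int, int, str, float]]:
        """(i, j, type, rest) rows in global indices, for export."""
        rows = []
        N = self.N
        for (i, j), r in zip(self.chain_bonds, self.chain_rest):
            rows.append((int(i), int(j), "chain", float(r)))
        for (i, j), r in zip(self.crosslink_bonds, self.crosslink_rest):
            rows.append((int(i), int(j), "crosslink", float(r)))
        for (i, j), r in zip(self.lamina_bonds, self.lamina_rest):
            rows.append((int(i) + N, int(j) + N, "lamina", float(r)))
        for (s, c), r in zip(self.linkage_bonds, self.linkage_rest):
            rows.append((int(s) + N, int(c), "linkage", float(r)))
        return rows

    def copy(self) -> "NucleusState":
        return NucleusState(
            chain=self.chain.copy(),
            lamina=self.lamina.copy(),
            chain_bonds=self.chain_bonds.copy(),
            crosslink_bonds=self.crosslink_bonds.copy(),
            lamina_bonds=self.lamina_bonds.copy(),
            linkage_bonds=self.linkage_bonds.copy(),
            chain_rest=self.chain_rest.copy(),
            crosslink_rest=self.crosslink_rest.copy(),
            lamina_rest=self.lamina_rest.copy(),
            linkage_rest=self.linkage_rest.copy(),
            motor_indices=None if self.motor_indices is None else self.motor_indices.copy(),
            motor_clocks=None if self.motor_clocks is None else self.motor_clocks.copy(),
            meta=dict(self.meta),
        )

    def with_crosslinks(self, crosslinks: np.ndarray) -> "NucleusState":
        """Same nucleus with a different (sub)set of crosslinks.

        Rest lengths are re-derived from the *built* chain coordinates, so a
        subset keeps exactly its original rest lengths.
        """
        out = self.copy()
        out.crosslink_bonds = np.asarray(crosslinks, dtype=np.int64).reshape(-1, 2)
        ref = self.meta.get("built_chain", self.chain)
        d = ref[out.crosslink_bonds[:, 1]] - ref[out.crosslink_bonds[:, 0]]
        out.crosslink_rest = np.linalg.norm(d, axis=1)
        return out

    def validate(self, z_target: float = 4.5, z_tol: float = 0.25) -> None:
        """Structural invariants: simple chain path, distinct non-adjacent
        crosslinks, connected lamina graph near the target coordination,
        finite positions."""
        if not (np.isfinite(self.chain).all() and np.isfinite(self.lamina).all()):
            raise ValueError("non-finite positions")
        N = self.N
        cb = self.chain_bonds
        if cb.shape[0] != N - 1 or not np.array_equal(cb[:, 1] - cb[:, 0], np.ones(N - 1, dtype=cb.dtype)):
            raise ValueError("chain bonds do not form a single unbranched path")
        xl = self.crosslink_bonds.reshape(-1, 2)
        if xl.size:
            if np.any(np.abs(xl[:, 1] - xl[:, 0]) < 2):
                raise ValueError("crosslink joins chain-adjacent monomers")
            pairs = {tuple(sorted(map(int, row))) for row in xl}
            if len(pairs) != xl.shape[0]:
                raise ValueError("duplicate crosslinks")
        z = 2.0 * self.lamina_bonds.shape[0] / max(self.M, 1)
        if abs(z - z_target) > z_tol:
            raise ValueError(f"lamina coordination {z:.2f} far from {z_target}")


def assemble_state(params: NucleusParams, seed: int) -> NucleusState:
    """Build shell, chain, crosslinks and linkages from one root seed.

    Uses named sub-streams so that paired runs (same seed, perturbed
    crosslink set) share the build and thermal noise exactly.
    """
    rb = stream_rng(seed, "build")
    shell_seed, chain_seed, xl_seed, lk_seed = rb.integers(0, 2**31 - 1, 4)
    shell, shell_bonds = build_lamina_shell(
        params.M_lam, z_target=params.z_target, seed=int(shell_seed), params=params
    )
    chain = init_chromatin(params.N, shell, seed=int(chain_seed), params=params)
    crosslinks = place_crosslinks(
        chain, params.N_C, seed=int(xl_seed), mode=params.crosslink_mode,
        params=params,
    )
    linkages = place_linkages(chain, shell, params.N_L, seed=int(lk_seed))

    def dist(posA, posB, pairs):
        if pairs.size == 0:
            return np.empty(0)
        return np.linalg.norm(posB[pairs[:, 1]] - posA[pairs[:, 0]], axis=1)

    if params.rest_length_mode == "as_built":
        chain_rest = dist(chain, chain, np.column_stack([np.arange(params.N - 1), np.arange(1, params.N)]))
    else:
        chain_rest = np.full(params.N - 1, params.sigma)
    state = NucleusState(
        chain=chain,
        lamina=shell,
        chain_bonds=np.column_stack(
            [np.arange(params.N - 1), np.arange(1, params.N)]
        ).astype(np.int64),
        crosslink_bonds=crosslinks,
        lamina_bonds=shell_bonds,
        linkage_bonds=linkages,
        chain_rest=chain_rest,
        crosslink_rest=dist(chain, chain, crosslinks),
        lamina_rest=dist(shell, shell, shell_bonds),
        linkage_rest=(
            np.linalg.norm(chain[linkages[:, 1]] - shell[linkages[:, 0]], axis=1)
            if linkages.size
            else np.empty(0)
        ),
        meta={"seed": int(seed), "built_chain": chain.copy()},
    )
    if params.motors.enabled:
        from .motors import assign_motors

        assign_motors(state, params.motors.N_m, stream_rng(seed, "motors"), params)
    state.validate(z_target=params.z_target)
    return state
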