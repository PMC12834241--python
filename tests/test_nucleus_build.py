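"""Nucleus construction: shell, chain, crosslinks, linkages."""

import numpy as np
import pytest

from orgnuc.nucleus import (
    NucleusParams,
    build_lamina_shell,
    init_chromatin,
    place_crosslinks,
    remove_crosslinks,
    place_linkages,
    crosslink_change_percent,
    assemble_state,
)
from orgnuc.nucleus.build import BuildError


class TestLaminaShell:
    def test_mean_coordination_near_target(self):
        pts, bonds = build_lamina_shell(500, seed=1)
        z = 2.0 * bonds.shape[0] / 500
        assert abs(z - 4.5) <= 0.2

    def test_connected_and_on_sphere(self):
        pts, bonds = build_lamina_shell(300, radius=1.0, seed=2)
        r = np.linalg.norm(pts, axis=1)
        assert np.allclose(r, 1.0, rtol=1e-6)

    def test_deterministic_per_seed(self):
        a = build_lamina_shell(400, seed=7)
        b = build_lamina_shell(400, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_rest_strains_zero_at_build(self, micro_state):
        d = micro_state.lamina[micro_state.lamina_bonds[:, 1]] - \
            micro_state.lamina[micro_state.lamina_bonds[:, 0]]
        L = np.linalg.norm(d, axis=1)
        assert np.allclose(L, micro_state.lamina_rest, rtol=1e-12)

    def test_unbracketable_coordination_rejected(self):
        with pytest.raises(BuildError):
            build_lamina_shell(200, z_target=50.0, seed=0)

    def test_too_few_monomers_rejected(self):
        with pytest.raises(BuildError):
            build_lamina_shell(8)


class TestChromatinInit:
    def test_chain_confined_and_weakly_overlapping(self):
        p = NucleusParams(N=50, M_lam=300, N_C=0, N_L=0, shell_spacing_factor=1.4)
        shell, _ = build_lamina_shell(300, seed=3, params=p)
        chain = init_chromatin(50, shell, seed=3, params=p)
        R = np.linalg.norm(shell, axis=1).mean()
        assert np.all(np.linalg.norm(chain, axis=1) <= R)
        from scipy.spatial import cKDTree

        dmin = cKDTree(chain).query(chain, k=2)[0][:, 1]
        # residual overlap below 0.1 sigma after the soft-core descent
        assert dmin.min() > 0.9 * p.sigma

    def test_deterministic_per_seed(self):
        p = NucleusParams(N=40, M_lam=300, N_C=0, N_L=0, shell_spacing_factor=1.4)
        shell, _ = build_lamina_shell(300, seed=3, params=p)
        a = init_chromatin(40, shell, seed=9, params=p)
        b = init_chromatin(40, shell, seed=9, params=p)
        assert np.array_equal(a, b)


class TestCrosslinks:
    def test_counts_and_constraints_uniform(self):
        rng = np.random.default_rng(0)
        chain = rng.standard_normal((200, 3))
        xl = place_crosslinks(chain, 80, seed=1, mode="uniform")
        assert xl.shape == (80, 2)
        assert np.all(np.abs(xl[:, 1] - xl[:, 0]) >= 2)
        assert len({tuple(r) for r in xl.tolist()}) == 80

    def test_proximal_mode_respects_capture_radius(self):
        # a compact random-walk chain has many molecular-range candidates
        p = NucleusParams(N=200, M_lam=300, N_C=0, N_L=0, shell_spacing_factor=1.4)
        shell, _ = build_lamina_shell(300, seed=3, params=p)
        chain = init_chromatin(200, shell, seed=3, params=p)
        xl = place_crosslinks(chain, 100, seed=1, params=p)
        assert xl.shape == (100, 2)
        assert np.all(np.abs(xl[:, 1] - xl[:, 0]) >= 2)
        d = np.linalg.norm(chain[xl[:, 1]] - chain[xl[:, 0]], axis=1)
        assert np.all(d <= 2.0 * p.sigma + 1e-12)

    def test_proximal_mode_fails_without_candidates(self):
        chain = np.arange(30)[:, None] * np.array([10.0, 0.0, 0.0])  # stretched
        with pytest.raises(BuildError):
            place_crosslinks(chain, 5, capture_radius=0.5)

    def test_zero_is_empty(self):
        chain = np.zeros((10, 3))
        assert place_crosslinks(chain, 0).shape == (0, 2)

    def test_infeasible_count_rejected(self):
        with pytest.raises(BuildError):
            place_crosslinks(np.zeros((5, 3)), 100)

    def test_removal_is_nested_across_k(self):
        chain = np.random.default_rng(1).standard_normal((100, 3))
        xl = place_crosslinks(chain, 50, seed=2, mode="uniform")
        r10 = {tuple(r) for r in remove_crosslinks(xl, 10, seed=5).tolist()}
        r20 = {tuple(r) for r in remove_crosslinks(xl, 20, seed=5).tolist()}
        assert len(r10) == 40 and len(r20) == 30
        assert r20 < r10  # strict subset: removal sets nest

    def test_zero_removal_is_identity(self):
        xl = np.array([[0, 5], [2, 9]])
        assert np.array_equal(remove_crosslinks(xl, 0, seed=1), xl)

    def test_negative_removal_rejected(self):
        with pytest.raises(ValueError):
            remove_crosslinks(np.zeros((3, 2), dtype=int), -1)

    def test_perturbation_percentage(self):
        # 10 removed of 2500 is the 0.4% comparison of the study
        assert crosslink_change_percent(10, 2500) == 0.4
        assert crosslink_change_percent(60, 2500) == pytest.approx(2.4)


class TestLinkages:
    def test_counts_and_uniqueness(self):
        rng = np.random.default_rng(3)
        p = NucleusParams(N=100, M_lam=300, N_C=0, N_L=30, shell_spacing_factor=1.4)
        shell, _ = build_lamina_shell(300, seed=3, params=p)
        chain = init_chromatin(100, shell, seed=3, params=p)
        lk = place_linkages(chain, shell, 30, seed=4)
        assert lk.shape == (30, 2)
        assert len(set(lk[:, 0].tolist())) == 30  # distinct shell monomers
        assert len(set(lk[:, 1].tolist())) == 30  # each chain monomer used once

    def test_zero_linkages(self):
        p = NucleusParams(N=20, M_lam=200, N_C=0, N_L=0, shell_spacing_factor=1.4)
        st = assemble_state(p, seed=1)
        assert st.linkage_bonds.shape[0] == 0


class TestAssembledState:
    def test_reference_ratios(self, micro_state):
        # fixture mirrors N_C/N = 0.5, N_L/N = 0.08
        assert micro_state.crosslink_bonds.shape[0] == 100
        assert micro_state.linkage_bonds.shape[0] == 16

    def test_validate_catches_broken_chain(self, micro_state):
        bad = micro_state.copy()
        bad.chain_bonds = bad.chain_bonds[:-2]
        with pytest.raises(ValueError):
            bad.validate()

    def test_assembly_deterministic(self, micro_nucleus_params, micro_state):
        again = assemble_state(micro_nucleus_params, seed=5)
        assert np.array_equal(again.chain, micro_state.chain)
        assert np.array_equal(again.lamina, micro_state.lamina)
        assert np.array_equal(again.crosslink_bonds, micro_state.crosslink_bonds)
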