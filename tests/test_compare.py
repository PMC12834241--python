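"""Comparison observables: displacement/strain differences, scaling fit,
contact maps."""

import numpy as np
import pytest

from orgnuc.compare import (
    DisplacementField,
    displacement_field,
    displacement_difference,
    mean_displacement_difference,
    distinguishability_onset,
    fit_scaling_law,
    spring_strain_map,
    mean_strain_difference,
    contact_map,
    contact_map_difference,
    mean_contacts_per_monomer,
    PairingError,
    DIFFERENCE_THRESHOLDS,
)

R_C = 0.05


def make_field(u):
    return DisplacementField(u=np.asarray(u, float), r_c=R_C, time=1.0)


def random_fields(rng, n_real, n_mono, scale=1.0, offset=0.0):
    return [
        make_field(offset + scale * rng.standard_normal((n_mono, 3)))
        for _ in range(n_real)
    ]


class TestDisplacementField:
    def test_frame_zero_is_null(self, micro_compression):
        f = displacement_field(micro_compression, 0, r_c=R_C)
        assert np.all(f.magnitudes == 0.0)

    def test_rigid_translation_magnitudes(self):
        u = np.tile([0.3, 0.0, -0.4], (10, 1))
        f = make_field(u)
        assert np.allclose(f.magnitudes, 0.5)
        assert np.allclose(f.magnitudes_rc, 10.0)

    def test_compression_moves_chromatin(self, micro_compression):
        f = displacement_field(micro_compression, -1, r_c=R_C)
        assert f.magnitudes.mean() > 0.0


class TestDisplacementDifference:
    def test_zero_perturbation_null(self):
        rng = np.random.default_rng(0)
        f = make_field(rng.standard_normal((50, 3)))
        d, mask = displacement_difference(f, f, threshold=0.5)
        assert np.all(d == 0.0) and not mask.any()

    def test_threshold_zero_keeps_all(self):
        rng = np.random.default_rng(1)
        a = make_field(rng.standard_normal((50, 3)))
        b = make_field(rng.standard_normal((50, 3)))
        _, mask = displacement_difference(a, b, threshold=0.0)
        assert mask.all()

    def test_mask_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        a = make_field(rng.standard_normal((200, 3)))
        b = make_field(rng.standard_normal((200, 3)))
        counts = [
            displacement_difference(a, b, th)[1].sum()
            for th in DIFFERENCE_THRESHOLDS
        ]
        assert all(c0 >= c1 for c0, c1 in zip(counts, counts[1:]))

    def test_unpaired_runs_refused(self):
        a = make_field(np.zeros((10, 3)))
        b = make_field(np.zeros((11, 3)))
        with pytest.raises(PairingError):
            displacement_difference(a, b, 0.1)


class TestMeanDisplacementDifference:
    def test_identical_ensembles_give_zero(self):
        rng = np.random.default_rng(3)
        fields = random_fields(rng, 5, 40)
        res = mean_displacement_difference(fields, fields, threshold_rc=3.5)
        assert res["y"] == 0.0
        assert res["zero_support"]

    def test_gating_convention(self):
        # differences all at 2 rc and 5 rc; a 3.5 rc gate keeps only the latter
        a = [make_field(np.zeros((10, 3)))]
        u = np.zeros((10, 3))
        u[:5, 0] = 2 * R_C
        u[5:, 0] = 5 * R_C
        b = [make_field(u)]
        res = mean_displacement_difference(a, b, threshold_rc=3.5)
        assert res["y"] == pytest.approx(5.0)
        ungated = mean_displacement_difference(a, b, threshold_rc=0.0)
        assert ungated["y"] == pytest.approx(3.5)

    def test_sem_shrinks_with_realizations(self):
        rng = np.random.default_rng(4)
        small = mean_displacement_difference(
            random_fields(rng, 8, 30), random_fields(rng, 8, 30), threshold_rc=0.0
        )
        large = mean_displacement_difference(
            random_fields(rng, 128, 30), random_fields(rng, 128, 30), threshold_rc=0.0
        )
        # resampling oracle: SEM ~ 1/sqrt(n); 16x the realizations -> ~4x smaller
        assert large["sem"] < small["sem"] / 2.0

    def test_permutation_safety(self):
        rng = np.random.default_rng(5)
        a = random_fields(rng, 3, 25)
        b = random_fields(rng, 3, 25)
        perm = rng.permutation(25)
        a_p = [make_field(f.u[perm]) for f in a]
        b_p = [make_field(f.u[perm]) for f in b]
        r1 = mean_displacement_difference(a, b, threshold_rc=0.0)
        r2 = mean_displacement_difference(a_p, b_p, threshold_rc=0.0)
        assert r1["y"] == pytest.approx(r2["y"], rel=1e-12)


class TestOnset:
    def test_cloned_ensembles_never_separate(self):
        strains = np.linspace(0, 0.4, 9)
        y = {0: np.zeros((6, 9)), 10: np.zeros((6, 9))}
        onset, _ = distinguishability_onset(y, strains)
        assert onset is None

    def test_injected_onset_recovered(self):
        rng = np.random.default_rng(6)
        strains = np.linspace(0.0, 0.40, 9)
        s_star = 0.35
        y = {0: 0.01 * rng.standard_normal((12, 9)) + 1.0}
        for lev in (10, 20):
            sig = np.where(strains >= s_star, 3.0, 0.0)
            y[lev] = 1.0 + sig + 0.01 * rng.standard_normal((12, 9))
        onset, curves = distinguishability_onset(y, strains)
        assert onset == pytest.approx(s_star)
        assert set(curves) == {0, 10, 20}
        assert curves[10]["mean"].shape == strains.shape

    def test_requires_two_levels(self):
        with pytest.raises(ValueError):
            distinguishability_onset({0: np.zeros((3, 4))}, np.zeros(4))


class TestScalingFit:
    def test_noiseless_recovery_to_four_decimals(self):
        x = np.arange(10, 70, 10, dtype=float)
        y = 3.84 + 0.001 * x**3.24
        fit = fit_scaling_law(x, y)
        assert fit.alpha == pytest.approx(3.24, abs=1e-4)
        assert fit.b == pytest.approx(3.84, abs=1e-4)

    @pytest.mark.parametrize("alpha", [1.5, 2.5, 3.24])
    def test_recovery_under_noise(self, alpha):
        rng = np.random.default_rng(int(alpha * 100))
        x = np.arange(10, 70, 10, dtype=float)
        y0 = 3.84 + 0.001 * x**alpha
        hits = 0
        for _ in range(40):
            y = y0 * (1 + 0.02 * rng.standard_normal(x.size))
            fit = fit_scaling_law(x, y)
            if abs(fit.alpha - alpha) < 3 * max(fit.alpha_err, 1e-6):
                hits += 1
        assert hits >= 32  # 3-sigma coverage on the large majority

    def test_linear_data_flagged(self):
        x = np.arange(1.0, 9.0)
        y = 2.0 + 0.5 * x
        fit = fit_scaling_law(x, y)
        assert fit.alpha == pytest.approx(1.0, abs=0.05)
        assert fit.not_faster_than_linear

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            fit_scaling_law([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            fit_scaling_law([-1, 1, 2, 3], [0, 1, 2, 3])


class TestSpringStrain:
    def test_zero_at_build_frame(self, micro_compression):
        m = spring_strain_map(micro_compression, 0)
        assert np.allclose(m.strains, 0.0, atol=1e-12)

    def test_strain_develops_under_compression(self, micro_compression):
        m = spring_strain_map(micro_compression, -1)
        assert np.abs(m.strains).max() > 0.0
        counts = m.tension_counts(0.30)
        assert counts["tension"] >= 0 and counts["compression"] >= 0

    def test_identical_runs_zero_difference(self, micro_compression):
        m = spring_strain_map(micro_compression, -1)
        res = mean_strain_difference([m], [m])
        assert res["y"] == 0.0


class TestContactMap:
    def test_distance_convention(self):
        # cutoff of two particle diameters = 4 r_c = 0.2
        pos = np.array([[0, 0, 0], [0.19, 0, 0], [0.60, 0, 0]])
        cm = contact_map(pos, cutoff=0.2)
        assert cm.matrix[0, 1] and cm.matrix[1, 0]
        assert not cm.matrix[0, 2]
        assert not cm.matrix[1, 2]  # 0.41 apart
        assert cm.matrix.diagonal().sum() == 0

    def test_chain_neighbor_convention(self):
        pos = np.array([[0, 0, 0], [0.1, 0, 0], [0.2, 0, 0]])
        with_n = contact_map(pos, 0.2, include_chain_neighbors=True)
        without = contact_map(pos, 0.2, include_chain_neighbors=False)
        assert with_n.matrix[0, 1]
        assert not without.matrix[0, 1]
        assert without.matrix[0, 2]  # distance 0.2 excluded? strictly inside only

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        pos = rng.uniform(0, 1, (100, 3))
        cutoff = 0.2
        cm = contact_map(pos, cutoff)
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        brute = {(i, j) for i in range(100) for j in range(i + 1, 100)
                 if d[i, j] < cutoff}
        assert cm.pairs() == brute

    def test_contacts_per_monomer_limits(self):
        empty = contact_map(np.array([[0, 0, 0], [5, 5, 5], [9, 0, 0]]), 0.1)
        assert mean_contacts_per_monomer(empty) == 0.0
        dense = contact_map(np.zeros((4, 3)) + np.arange(4)[:, None] * 1e-4, 1.0)
        assert mean_contacts_per_monomer(dense) == pytest.approx(3.0)

    def test_difference_identical_maps(self):
        rng = np.random.default_rng(8)
        pos = rng.uniform(0, 1, (50, 3))
        cm = contact_map(pos, 0.3)
        diff = contact_map_difference(cm, cm)
        assert diff["n_ref_only"] == 0 and diff["n_pert_only"] == 0
        assert diff["n_shared"] == cm.n_contacts

    def test_difference_disjoint_maps(self):
        a = contact_map(np.array([[0, 0, 0], [0.1, 0, 0], [5, 5, 5], [9, 9, 9]]), 0.2)
        b = contact_map(np.array([[0, 0, 0], [3, 0, 0], [5, 5, 5], [5.1, 5, 5]]), 0.2)
        diff = contact_map_difference(a, b)
        assert diff["n_shared"] == 0
        assert diff["n_ref_only"] == a.n_contacts
        assert diff["n_pert_only"] == b.n_contacts

    def test_dimension_mismatch_rejected(self):
        a = contact_map(np.zeros((3, 3)), 0.1)
        b = contact_map(np.zeros((4, 3)), 0.1)
        with pytest.raises(ValueError):
            contact_map_difference(a, b)
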