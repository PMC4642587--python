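"""Kabsch superposition, distance-matrix mean structure and ensemble RMSDs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from nmrens.ensemble_stats import (
    average_distance_matrix,
    back_project,
    ensemble_rmsd,
    fragment_rmsd,
    kabsch,
    per_residue_rmsd,
    unbiased_mean,
)
from nmrens.recovery import (
    mean_structure_recovery,
    quaternion_grid_rmsd,
    sigma_profile_correlation,
)
from nmrens.structure_io import Ensemble, Selection, select_coords
from nmrens.synthetic import EnsembleSpec, make_template, perturb_ensemble


def random_rotation(seed):
    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()


class TestKabsch:
    def test_rigid_transform_gives_zero_rmsd(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 3))
        R = random_rotation(1)
        Y = X @ R.T + np.array([1.0, -2.0, 3.0])
        rot, t, rmsd = kabsch(X, Y)
        assert rmsd < 1e-9
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        X, Y = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        assert kabsch(X, Y)[2] == pytest.approx(kabsch(Y, X)[2], abs=1e-10)

    def test_displaced_tetrahedron_matches_quaternion_oracle(self):
        X = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float) / np.sqrt(3)
        Y = X.copy()
        Y[0] += np.array([1.0, 0.0, 0.0])
        _, _, r_svd = kabsch(X, Y)
        r_grid = quaternion_grid_rmsd(X, Y, seed=3)
        assert r_svd == pytest.approx(r_grid, abs=1e-3)

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(4)
        X, Y = rng.normal(size=(12, 3)), rng.normal(size=(12, 3))
        _, _, r_svd = kabsch(X, Y)
        rot, ref_rssd = Rotation.align_vectors(
            X - X.mean(0), Y - Y.mean(0)
        )
        assert r_svd == pytest.approx(ref_rssd / np.sqrt(12), rel=1e-6)

    def test_collinear_points_rejected(self):
        X = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError, match="collinear"):
            kabsch(X, X + 1.0)

    def test_rotation_always_proper(self):
        # mirror-image input must not produce a reflection
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 3))
        Y = X * np.array([1.0, 1.0, -1.0])
        rot, _, _ = kabsch(X, Y)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)


class TestAverageDistanceMatrix:
    def test_single_conformer_is_own_matrix(self, helix_ensemble):
        sel = Selection(((1, 12),), "CA")
        D = average_distance_matrix(helix_ensemble, sel)
        coords, _ = select_coords(helix_ensemble, sel)
        direct = np.linalg.norm(coords[0][:, None] - coords[0][None], axis=-1)
        np.testing.assert_allclose(D, direct, atol=1e-12)

    def test_entrywise_arithmetic_mean(self):
        # two conformers with one atom pair at 2 A and 4 A -> entry 3 A
        from nmrens.structure_io import Atom, Conformer

        def conf(mid, d):
            atoms = [
                Atom(1, "CA", "C", "", "ALA", "A", 1, (0.0, 0.0, 0.0)),
                Atom(2, "CA", "C", "", "ALA", "A", 2, (d, 0.0, 0.0)),
                Atom(3, "CA", "C", "", "ALA", "A", 3, (0.0, d, 0.0)),
            ]
            return Conformer(mid, atoms)

        ens = Ensemble([conf(1, 2.0), conf(2, 4.0)], {1: "ALA", 2: "ALA", 3: "ALA"})
        D = average_distance_matrix(ens, Selection(((1, 3),), "CA"))
        assert D[0, 1] == pytest.approx(3.0)
        assert D[1, 0] == pytest.approx(3.0)
        assert np.allclose(np.diag(D), 0.0)

    def test_matches_naive_double_loop(self, cxxc_ensemble):
        sel = Selection(((175, 185),), "CA")
        D = average_distance_matrix(cxxc_ensemble, sel)
        coords, _ = select_coords(cxxc_ensemble, sel)
        n = coords.shape[1]
        naive = np.zeros((n, n))
        for m in range(coords.shape[0]):
            for i in range(n):
                for j in range(n):
                    naive[i, j] += np.sqrt(((coords[m, i] - coords[m, j]) ** 2).sum())
        naive /= coords.shape[0]
        np.testing.assert_allclose(D, naive, atol=1e-10)


class TestBackProjection:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=4, max_value=50), st.integers(min_value=0, max_value=10**6))
    def test_exact_distance_matrix_recovered_up_to_isometry(self, n, seed):
        pts = np.random.default_rng(seed).normal(size=(n, 3)) * 5.0
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        emb = back_project(D).coords
        D2 = np.linalg.norm(emb[:, None] - emb[None], axis=-1)
        assert np.abs(D - D2).max() < 1e-6

    def test_planar_set_reports_vanishing_third_eigenvalue(self):
        rng = np.random.default_rng(8)
        pts = np.column_stack([rng.normal(size=(10, 2)) * 3.0, np.zeros(10)])
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        ms = back_project(D)
        assert abs(ms.eigenvalues[2]) < 1e-8 * ms.eigenvalues[0]

    def test_collinear_set_rejected(self):
        pts = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        with pytest.raises(ValueError, match="degenerate"):
            back_project(D)

    def test_asymmetric_matrix_rejected(self):
        D = np.arange(9.0).reshape(3, 3)
        with pytest.raises(ValueError):
            back_project(D)

    def test_centroid_at_origin(self):
        pts = np.random.default_rng(9).normal(size=(7, 3))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        ms = back_project(D)
        np.testing.assert_allclose(ms.coords.mean(axis=0), 0.0, atol=1e-10)


class TestUnbiasedMean:
    def test_identical_copies_reproduce_the_copy(self, helix_ensemble):
        conf = helix_ensemble.conformers[0]
        ens = Ensemble([conf, conf, conf], helix_ensemble.sequence)
        sel = Selection(((1, 12),), "backbone")
        mean = unbiased_mean(ens, sel)
        coords, _ = select_coords(ens, sel)
        _, _, rmsd = kabsch(coords[0], mean.coords)
        assert rmsd < 1e-6

    def test_invariant_under_conformer_order(self, cxxc_ensemble):
        sel = Selection(((175, 196),), "backbone")
        mean_fwd = unbiased_mean(cxxc_ensemble, sel)
        reversed_ens = Ensemble(
            list(reversed(cxxc_ensemble.conformers)), cxxc_ensemble.sequence
        )
        mean_rev = unbiased_mean(reversed_ens, sel)
        _, _, rmsd = kabsch(mean_fwd.coords, mean_rev.coords)
        assert rmsd < 1e-6

    def test_recovers_generator_template(self):
        assert mean_structure_recovery(seed=3) < 0.15

    def test_requires_two_conformers(self, helix_ensemble):
        with pytest.raises(ValueError):
            unbiased_mean(helix_ensemble, Selection(((1, 12),), "CA"))


class TestEnsembleRmsd:
    def test_identical_copies_give_zero(self, helix_ensemble):
        conf = helix_ensemble.conformers[0]
        ens = Ensemble([conf, conf], helix_ensemble.sequence)
        report = ensemble_rmsd(ens, Selection(((1, 12),), "backbone"))
        assert np.all(report.per_model_rmsd < 1e-6)

    def test_against_independent_classical_scaling_route(self, cxxc_ensemble):
        """Cross-check per-model RMSDs against an implementation assembled
        from scipy primitives only (eigh on the centred Gram matrix,
        Rotation.align_vectors for superposition)."""
        from scipy.linalg import eigh

        sel = Selection(((175, 190),), "CA")
        report = ensemble_rmsd(cxxc_ensemble, sel)
        coords, _ = select_coords(cxxc_ensemble, sel)
        M, n, _ = coords.shape
        D = np.zeros((n, n))
        for m in range(M):
            D += np.linalg.norm(coords[m][:, None] - coords[m][None], axis=-1)
        D /= M
        J = np.eye(n) - 1.0 / n
        w, v = eigh(-0.5 * J @ (D**2) @ J)
        mean = v[:, -3:][:, ::-1] * np.sqrt(np.maximum(w[-3:][::-1], 0))
        # resolve the reflection exactly as documented: against conformer 1
        best = None
        for mirror in (mean, mean * [1, 1, -1]):
            _, rssd = Rotation.align_vectors(
                coords[0] - coords[0].mean(0), mirror - mirror.mean(0)
            )
            r = rssd / np.sqrt(n)
            if best is None or r < best[1]:
                best = (mirror, r)
        mean = best[0]
        expected = []
        for m in range(M):
            _, rssd = Rotation.align_vectors(
                mean - mean.mean(0), coords[m] - coords[m].mean(0)
            )
            expected.append(rssd / np.sqrt(n))
        np.testing.assert_allclose(report.per_model_rmsd, expected, atol=1e-8)

    def test_mean_not_above_rms_summary(self, cxxc_ensemble):
        report = ensemble_rmsd(cxxc_ensemble, Selection(((175, 196),), "all_heavy"))
        assert report.ensemble_rmsd_mean <= report.ensemble_rmsd_rms + 1e-12

    def test_invariant_under_rigid_motion_of_a_conformer(self, cxxc_ensemble):
        sel = Selection(((175, 196),), "backbone")
        base = ensemble_rmsd(cxxc_ensemble, sel)
        from nmrens.structure_io import Atom, Conformer

        R = random_rotation(11)
        t = np.array([5.0, -3.0, 2.0])
        moved = []
        for i, conf in enumerate(cxxc_ensemble.conformers):
            if i != 4:
                moved.append(conf)
                continue
            atoms = [
                Atom(a.serial, a.name, a.element, a.alt_loc, a.res_name, a.chain,
                     a.res_seq, tuple(R @ np.array(a.coords) + t))
                for a in conf.atoms
            ]
            moved.append(Conformer(conf.model_id, atoms))
        report = ensemble_rmsd(Ensemble(moved, cxxc_ensemble.sequence), sel)
        np.testing.assert_allclose(report.per_model_rmsd, base.per_model_rmsd, atol=1e-8)


class TestFragmentRmsd:
    def test_identical_selection_gives_zero(self, cxxc_ensemble):
        sel = Selection(((176, 182),), "backbone")
        assert fragment_rmsd(cxxc_ensemble.conformers[0], sel, sel) < 1e-12

    def test_two_ideal_helical_fragments_superpose_exactly(self):
        conf = make_template(20, "helix")
        a = Selection(((3, 9),), "backbone_no_O")
        b = Selection(((11, 17),), "backbone_no_O")
        assert fragment_rmsd(conf, a, b) < 1e-6

    def test_count_mismatch_rejected(self, cxxc_ensemble):
        with pytest.raises(ValueError, match="atom counts"):
            fragment_rmsd(
                cxxc_ensemble.conformers[0],
                Selection(((176, 182),), "backbone"),
                Selection(((188, 195),), "backbone"),
            )


def test_per_residue_rmsd_tracks_displacement_profile():
    assert sigma_profile_correlation(seed=1) > 0.9
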