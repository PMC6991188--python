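"""PCA fitting, variance accounting, projection of training and new data."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trajpca.io import Trajectory
from trajpca.model import (
    PathPCA,
    PathPCAResults,
    RepresentationMatrix,
    build_representation,
    fit_pca,
)
from trajpca.synthetic import add_rigid_motion, make_stretch, make_torsion


def covariance_eig_oracle(X):
    """Brute-force reference: form the covariance matrix explicitly and
    diagonalize it (independent of the SVD route used by fit_pca)."""
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


def rep_from_array(X, n_atoms=None):
    n_atoms = n_atoms or (X.shape[1] // 3)
    return RepresentationMatrix(
        data=X,
        representation="cartesians",
        mass_weighted=False,
        n_atoms=n_atoms,
        elements=("X",) * n_atoms,
        reference_frame=np.zeros((n_atoms, 3)),
    )


class TestFitPCA:
    def test_rank_one_line_segment(self, rng):
        direction = rng.normal(size=12)
        X = np.outer(np.linspace(0, 1, 9), direction) + rng.normal(size=12)
        res = fit_pca(rep_from_array(X))
        assert res.rank == 1
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(res.eigenvalues[1:] == 0)

    @given(st.integers(3, 20), st.integers(2, 12), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_explicit_covariance_oracle(self, n, p, seed):
        X = np.random.default_rng(seed).normal(size=(n, p * 3))
        res = fit_pca(rep_from_array(X, n_atoms=p))
        evals, evecs = covariance_eig_oracle(X)
        k = min(n - 1, X.shape[1])
        np.testing.assert_allclose(res.eigenvalues[:k], evals[:k], atol=1e-8)
        for i in range(k):  # up to sign
            dot = abs(res.components[i] @ evecs[:, i])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_matches_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.decomposition")
        X = rng.normal(size=(15, 9))
        res = fit_pca(rep_from_array(X))
        sk = sklearn.PCA().fit(X)
        np.testing.assert_allclose(
            res.eigenvalues[: sk.n_components_], sk.explained_variance_, atol=1e-10
        )
        np.testing.assert_allclose(
            res.variance_fractions[: sk.n_components_],
            sk.explained_variance_ratio_,
            atol=1e-10,
        )

    def test_component_orthonormality_and_spectrum_invariants(self, rng):
        X = rng.normal(size=(10, 12))
        res = fit_pca(rep_from_array(X, n_atoms=4))
        G = res.components @ res.components.T
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-10)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert np.all(res.eigenvalues >= 0)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-10)

    def test_deterministic_sign_convention(self, rng):
        X = rng.normal(size=(8, 6))
        res = fit_pca(rep_from_array(X, n_atoms=2))
        for row in res.components[: res.rank]:
            assert row[np.argmax(np.abs(row))] > 0

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="at least two frames"):
            fit_pca(rep_from_array(np.zeros((1, 6)), n_atoms=2))


class TestGoodnessOfFit:
    def test_full_rank_is_unity_and_partial_sums(self, rng):
        X = rng.normal(size=(7, 6))
        res = fit_pca(rep_from_array(X, n_atoms=2))
        assert res.goodness_of_fit(res.rank) == pytest.approx(1.0, abs=1e-10)
        assert res.goodness_of_fit(2) == pytest.approx(
            res.variance_fractions[:2].sum()
        )

    def test_two_eigenvalue_example(self):
        # spectrum {3, 1} -> one component carries 3/4 of the variance
        t = np.linspace(-1, 1, 50)
        X = np.zeros((50, 6))
        X[:, 0] = t * np.sqrt(3.0 / np.var(t, ddof=1))
        X[:, 1] = np.sin(np.pi * t) / np.std(np.sin(np.pi * t), ddof=1)
        X[:, 1] -= X[:, 0] * (X[:, 0] @ X[:, 1]) / (X[:, 0] @ X[:, 0])
        X[:, 1] /= np.std(X[:, 1], ddof=1)
        res = fit_pca(rep_from_array(X, n_atoms=2))
        assert res.goodness_of_fit(1) == pytest.approx(0.75, abs=1e-6)

    def test_out_of_range_rejected(self, rng):
        res = fit_pca(rep_from_array(rng.normal(size=(5, 6)), n_atoms=2))
        with pytest.raises(ValueError):
            res.goodness_of_fit(0)
        with pytest.raises(ValueError):
            res.goodness_of_fit(res.rank + 1)


class TestTransform:
    def test_scores_match_dot_product_oracle(self, rng):
        X = rng.normal(size=(9, 12))
        res = fit_pca(rep_from_array(X, n_atoms=4))
        path = res.transform(n_dim=3)
        expected = np.empty((9, 3))
        for k in range(9):  # explicit per-frame (x - mean) . W_i loop
            for i in range(3):
                expected[k, i] = (X[k] - res.mean) @ res.components[i]
        np.testing.assert_allclose(path.scores, expected, atol=1e-10)

    def test_mean_frame_scores_to_zero(self, rng):
        X = rng.normal(size=(6, 6))
        res = fit_pca(rep_from_array(X, n_atoms=2))
        rep = rep_from_array(np.tile(res.mean, (1, 1)), n_atoms=2)
        np.testing.assert_allclose(
            res.transform(rep, n_dim=2).scores, 0.0, atol=1e-10
        )

    def test_full_rank_scores_reconstruct_data(self, rng):
        X = rng.normal(size=(8, 9))
        res = fit_pca(rep_from_array(X, n_atoms=3))
        k = res.rank
        path = res.transform(n_dim=k)
        back = path.scores @ res.components[:k] + res.mean
        np.testing.assert_allclose(back, X, atol=1e-8)

    def test_training_score_variance_tracks_eigenvalues(self, random_trajectory):
        res = PathPCA(random_trajectory, "cartesians").fit()
        path = res.transform(n_dim=res.rank)
        np.testing.assert_allclose(
            np.var(path.scores, axis=0, ddof=1), res.eigenvalues[: res.rank], atol=1e-10
        )

    def test_metadata_mismatch_rejected(self, random_trajectory):
        res = PathPCA(random_trajectory, "cartesians").fit()
        other = build_representation(random_trajectory, "distances")
        with pytest.raises(ValueError, match="metadata mismatch"):
            res.transform(other, n_dim=1)


class TestTransformNew:
    def test_training_trajectory_projects_identically(self, random_trajectory):
        for rep in ("cartesians", "distances"):
            res = PathPCA(random_trajectory, rep).fit()
            a = res.transform(n_dim=2).scores
            b = res.transform_new(random_trajectory, n_dim=2).scores
            np.testing.assert_allclose(b, a, atol=1e-8)

    def test_frame_equal_to_training_frame_gets_its_score(self, random_trajectory):
        res = PathPCA(random_trajectory, "distances").fit()
        train = res.transform(n_dim=2).scores
        single = random_trajectory[4]
        new = res.transform_new(single, n_dim=2).scores
        np.testing.assert_allclose(new[0], train[4], atol=1e-8)

    def test_new_frames_match_dot_product_oracle(self, random_trajectory, rng):
        res = PathPCA(random_trajectory, "distances").fit()
        wobble = Trajectory(
            random_trajectory.elements,
            random_trajectory.coords + rng.normal(scale=0.05, size=random_trajectory.coords.shape),
        )
        got = res.transform_new(wobble, n_dim=2).scores
        from trajpca.geometry import squared_distance_vector

        for k in range(wobble.n_frames):
            x = squared_distance_vector(wobble.coords[k])
            for i in range(2):
                assert got[k, i] == pytest.approx(
                    (x - res.mean) @ res.components[i], abs=1e-8
                )

    def test_atom_mismatch_rejected(self, random_trajectory, rng):
        res = PathPCA(random_trajectory, "distances").fit()
        smaller = Trajectory(("X",) * 4, rng.normal(size=(3, 4, 3)))
        with pytest.raises(ValueError, match="does not match"):
            res.transform_new(smaller, n_dim=1)


class TestDistancesInvariance:
    def test_spectrum_invariant_under_per_frame_rigid_motions(self):
        traj = make_stretch(n_frames=15, seed=3)
        contaminated = add_rigid_motion(traj, seed=11)
        a = PathPCA(traj, "distances").fit()
        b = PathPCA(contaminated, "distances").fit()
        np.testing.assert_allclose(b.eigenvalues, a.eigenvalues, atol=1e-10)
        np.testing.assert_allclose(
            b.variance_fractions, a.variance_fractions, atol=1e-10
        )

    def test_rigid_only_trajectory_has_zero_distance_spread(self, rng):
        one = Trajectory(("X",) * 5, rng.normal(size=(1, 5, 3)))
        rigid = add_rigid_motion(Trajectory(one.elements, np.repeat(one.coords, 10, 0)), seed=5)
        rep = build_representation(rigid, "distances")
        assert np.ptp(rep.data, axis=0).max() < 1e-10
        # and the aligned-Cartesian variance is numerically zero too
        repc = build_representation(rigid, "cartesians")
        assert np.var(repc.data, axis=0).max() < 1e-16


class TestSerialization:
    def test_save_load_round_trip_bit_exact(self, tmp_path, random_trajectory):
        res = PathPCA(random_trajectory, "distances").fit()
        p = res.save(tmp_path / "model.npz")
        loaded = PathPCAResults.load(p)
        np.testing.assert_array_equal(loaded.mean, res.mean)
        np.testing.assert_array_equal(loaded.components, res.components)
        np.testing.assert_array_equal(loaded.eigenvalues, res.eigenvalues)
        assert loaded.rep_matrix.metadata_matches(res.rep_matrix)
        # projection works identically after reload
        np.testing.assert_array_equal(
            loaded.transform_new(random_trajectory, n_dim=2).scores,
            res.transform_new(random_trajectory, n_dim=2).scores,
        )


class TestTorsionOrdering:
    def test_distances_beat_cartesians_on_pure_torsion(self):
        traj = make_torsion()
        gof_d = PathPCA(traj, "distances").fit().goodness_of_fit(1)
        gof_c = PathPCA(traj, "cartesians").fit().goodness_of_fit(1)
        assert gof_d > gof_c
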