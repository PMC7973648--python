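"""Relationship kernels: hand-computed values, PSD/symmetry invariants,
Gaussian kernels and bandwidth estimation."""

import numpy as np
import pandas as pd
import pytest

import hybridpred as hp
from hybridpred.containers import DistanceMatrix, OmicsMatrix
from hybridpred.kernels import DEFAULT_BANDWIDTH_GRID


def geno(arr, ids=None):
    arr = np.asarray(arr, dtype=float)
    ids = ids or [f"i{k}" for k in range(arr.shape[0])]
    return OmicsMatrix(pd.DataFrame(arr, index=ids), "genomic")


class TestAdditive:
    def test_vanraden_hand_example(self):
        # individuals (0,0) and (2,2); p = (0.5, 0.5); W = +/-1; denom = 1
        K = hp.additive_kernel(geno([[0, 0], [2, 2]]))
        np.testing.assert_allclose(K.matrix, [[2, -2], [-2, 2]], atol=1e-12)

    def test_duplicated_individuals_identical_rows(self, rng):
        M = rng.integers(0, 3, size=(6, 40)).astype(float)
        M[3] = M[0]
        K = hp.additive_kernel(geno(M))
        np.testing.assert_allclose(K.matrix[0], K.matrix[3], atol=1e-12)

    def test_mean_diagonal_near_one_on_hwe_panel(self, rng):
        p = rng.uniform(0.1, 0.9, 500)
        M = rng.binomial(2, p, size=(200, 500)).astype(float)
        K = hp.additive_kernel(geno(M))
        assert np.mean(np.diag(K.matrix)) == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_columns_dropped_with_warning(self):
        M = np.array([[0, 0.0], [2, 0.0]])
        with pytest.warns(UserWarning, match="monomorphic"):
            K = hp.additive_kernel(geno(M))
        # only the polymorphic column remains: W = (-1, 1), denom = 0.5
        np.testing.assert_allclose(K.matrix, [[2, -2], [-2, 2]], atol=1e-12)

    def test_all_monomorphic_error(self):
        with pytest.raises(ValueError):
            hp.additive_kernel(geno([[2.0, 0.0], [2.0, 0.0]]))

    def test_feature_order_invariance(self, rng):
        M = rng.integers(0, 3, size=(10, 30)).astype(float)
        perm = rng.permutation(30)
        K1 = hp.additive_kernel(geno(M))
        K2 = hp.additive_kernel(geno(M[:, perm]))
        np.testing.assert_allclose(K1.matrix, K2.matrix, atol=1e-12)

    def test_quantitative_layer_trace_normalized(self, rng):
        om = OmicsMatrix(pd.DataFrame(rng.normal(size=(15, 50))), "transcriptomic")
        K = hp.additive_kernel(om)
        assert np.mean(np.diag(K.matrix)) == pytest.approx(1.0)


class TestDominance:
    def test_su_hand_example_with_given_frequency(self):
        # one marker, dosages (1, 0), p = 0.5: W = (0.5, -0.5), denom = 0.25
        K = hp.dominance_kernel(geno([[1.0], [0.0]]), freq=np.array([0.5]))
        np.testing.assert_allclose(K.matrix, [[1, -1], [-1, 1]], atol=1e-12)

    def test_fully_homozygous_panel_error(self):
        with pytest.raises(ValueError, match="heterozygous"):
            hp.dominance_kernel(geno([[0, 2.0], [2, 0.0]]))

    def test_invariant_to_parent_label_swap(self, small_ds):
        # heterozygosity is symmetric in the parents, so the hybrid panel's
        # dominance kernel cannot depend on which parent is the tester
        K = hp.dominance_kernel(small_ds.hybrid_genotypes)
        assert np.max(np.abs(K.matrix - K.matrix.T)) < 1e-12


class TestEpistatic:
    def test_identity_maps_to_identity(self):
        A = hp.RelationshipKernel(np.eye(4), "additive", "genomic",
                                  [f"i{k}" for k in range(4)])
        E = hp.epistatic_kernel(A)
        np.testing.assert_allclose(E.matrix, np.eye(4), atol=1e-12)

    def test_elementwise_square_before_rescaling(self):
        M = np.array([[1.0, -2.0], [-2.0, 5.0]])
        A = hp.RelationshipKernel(M, "additive", "genomic", ["a", "b"])
        E = hp.epistatic_kernel(A)
        raw = M * M
        np.testing.assert_allclose(E.matrix, raw / np.mean(np.diag(raw)), atol=1e-12)

    def test_psd_preserved_on_random_draws(self, rng):
        for _ in range(5):
            B = rng.normal(size=(8, 12))
            A = hp.RelationshipKernel(B @ B.T + 1e-6 * np.eye(8), "additive",
                                      "genomic", [f"i{k}" for k in range(8)])
            assert hp.epistatic_kernel(A).min_eigenvalue() > -1e-10

    def test_requires_additive_input(self):
        G = hp.RelationshipKernel(np.eye(3), "gaussian", "genomic",
                                  ["a", "b", "c"])
        with pytest.raises(ValueError):
            hp.epistatic_kernel(G)


class TestDistancesAndGaussian:
    def test_three_four_five_triangle(self):
        om = OmicsMatrix(pd.DataFrame([[0.0, 0.0], [3.0, 4.0]]), "metabolic")
        D = hp.euclidean_distances(om)
        assert D.matrix[0, 1] == pytest.approx(5.0)

    def test_identical_rows_zero_distance(self):
        om = OmicsMatrix(pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]]),
                         "metabolic")
        D = hp.euclidean_distances(om)
        assert D.matrix[0, 1] == 0.0

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(6, 4))
        perm = rng.permutation(6)
        D1 = hp.euclidean_distances(OmicsMatrix(pd.DataFrame(X), "metabolic"))
        D2 = hp.euclidean_distances(OmicsMatrix(
            pd.DataFrame(X[perm], index=perm), "metabolic"))
        np.testing.assert_allclose(D2.matrix, D1.matrix[np.ix_(perm, perm)],
                                   atol=1e-12)

    def test_gaussian_closed_form_and_limits(self):
        D = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), "genomic",
                           ["a", "b"])
        assert D.scaled_sq[0, 1] == pytest.approx(1.0)  # off-diag mean scaling
        K = hp.gaussian_kernel(D, 1.0)
        assert K.matrix[0, 0] == 1.0
        assert K.matrix[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)
        K0 = hp.gaussian_kernel(D, 1e-12)
        np.testing.assert_allclose(K0.matrix, 1.0, atol=1e-9)
        with pytest.raises(ValueError):
            hp.gaussian_kernel(D, 0.0)

    def test_gaussian_monotone_in_distance(self, rng):
        X = rng.normal(size=(10, 5))
        D = hp.euclidean_distances(OmicsMatrix(pd.DataFrame(X), "metabolic"))
        K = hp.gaussian_kernel(D, 0.7)
        iu = np.triu_indices(10, 1)
        order = np.argsort(D.scaled_sq[iu])
        assert np.all(np.diff(K.matrix[iu][order]) <= 1e-12)


class TestBandwidth:
    def test_singleton_grid_returned(self, rng):
        X = rng.normal(size=(30, 5))
        D = hp.euclidean_distances(OmicsMatrix(pd.DataFrame(X), "genomic"))
        prof = hp.estimate_bandwidth(D, rng.normal(size=30), grid=[0.3])
        assert prof.best == 0.3

    def test_recovery_within_one_grid_step(self):
        from hybridpred.experiments import bandwidth_recovery
        df = bandwidth_recovery(n=100, n_seeds=5, h_true=0.5, seed=3)
        assert np.median(df["step_offset"]) <= 1

    def test_pure_noise_prefers_smallest_h(self, rng):
        X = rng.normal(size=(60, 8))
        D = hp.euclidean_distances(OmicsMatrix(pd.DataFrame(X), "genomic"))
        y = rng.normal(size=60)
        prof = hp.estimate_bandwidth(D, y, grid=DEFAULT_BANDWIDTH_GRID,
                                     tie_tol=2.0)
        # profile is flat within a couple of log-lik units: smallest h wins
        assert prof.best == min(DEFAULT_BANDWIDTH_GRID)
        assert max(prof.loglik) - min(
            ll for ll in prof.loglik if np.isfinite(ll)) < 4.0
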