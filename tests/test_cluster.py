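"""PCA, the four clustering algorithms, validation measures and MDS."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from soundscapemap.cluster import (classical_mds, cluster, run_pca,
                                   select_dimensions, validate_clusterings,
                                   variable_contributions)
from soundscapemap.descriptors import FeatureMatrix


def _fm(X, prefix="F"):
    df = pd.DataFrame(X, columns=[f"{prefix}{j}_mean" for j in range(X.shape[1])],
                      index=[f"S{i:02d}" for i in range(X.shape[0])])
    df.index.name = "site_id"
    return FeatureMatrix(df)


class TestPCA:
    def test_collinear_features_explained_by_one_dim(self, rng):
        x = rng.normal(size=20)
        fm = _fm(np.column_stack([x, 3 * x + 1]))
        pca = run_pca(fm)
        assert pca.explained_variance_pct[0] == pytest.approx(100.0)

    def test_standardized_eigenvalues_sum_to_p(self, rng):
        X = rng.normal(size=(16, 35))
        pca = run_pca(_fm(X))
        assert pca.eigenvalues.sum() == pytest.approx(35.0)
        assert pca.explained_variance_pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_loadings_orthonormal(self, rng):
        pca = run_pca(_fm(rng.normal(size=(16, 8))))
        np.testing.assert_allclose(pca.loadings.T @ pca.loadings,
                                   np.eye(8), atol=1e-9)

    def test_reconstruction_error_decreases_with_dims(self, rng):
        X = rng.normal(size=(16, 35))
        pca = run_pca(_fm(X))
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        errs = []
        for d in (1, 3, 8, 16):
            recon = pca.scores[:, :d] @ pca.loadings[:, :d].T
            errs.append(np.linalg.norm(Z - recon))
        assert all(a > b for a, b in zip(errs, errs[1:]))

    def test_constant_column_dropped_with_warning(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 4.2
        with pytest.warns(UserWarning, match="constant"):
            pca = run_pca(_fm(X))
        assert len(pca.feature_names) == 2


class TestContributions:
    def test_columns_sum_to_100(self, rng):
        pca = run_pca(_fm(rng.normal(size=(12, 10))))
        tab = variable_contributions(pca).table
        np.testing.assert_allclose(tab.sum(axis=0), 100.0, atol=1e-6)

    def test_equal_loadings_split_evenly(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        # two features = same signal: dim 1 loads them equally -> 50/50
        fm = _fm(np.column_stack([x, x + rng.normal(0, 1e-9, 30)]))
        tab = variable_contributions(run_pca(fm), dims=1).table
        assert tab["Dim1"].to_numpy() == pytest.approx([50.0, 50.0], abs=0.1)

    def test_descriptor_grouping_aggregates(self, rng):
        X = rng.normal(size=(10, 4))
        df = pd.DataFrame(X, columns=["ACI_mean", "ACI_sd", "H_mean", "H_sd"],
                          index=[f"S{i}" for i in range(10)])
        df.index.name = "site_id"
        tab = variable_contributions(run_pca(FeatureMatrix(df))).table
        assert list(tab.index) == ["ACI", "H"]


class TestSelectDimensions:
    def _pca_with_pcts(self, pcts):
        pca = run_pca(_fm(np.random.default_rng(0).normal(size=(12, len(pcts)))))
        pca.explained_variance_pct = np.asarray(pcts, dtype=float)
        pca.cumulative_pct = np.cumsum(pca.explained_variance_pct)
        return pca

    def test_published_style_variance_profile_retains_three(self):
        pcts = [54.1, 15.8, 8.3, 6.0, 4.0, 3.0, 2.8, 2.0, 2.0, 2.0]
        assert select_dimensions(self._pca_with_pcts(pcts), 78.0) == 3

    def test_first_component_alone_can_suffice(self):
        pcts = [54.1, 15.8, 8.3, 21.8]
        assert select_dimensions(self._pca_with_pcts(pcts), 50.0) == 1

    def test_equal_variances_cumulative(self):
        assert select_dimensions(self._pca_with_pcts([10.0] * 10), 95.0) == 10

    def test_unreachable_target_warns_and_returns_all(self):
        pca = self._pca_with_pcts([50.0, 30.0])
        with pytest.warns(UserWarning, match="unreachable"):
            assert select_dimensions(pca, 101.0) == 2


class TestClusterAlgorithms:
    def test_kmeans_recovers_separated_clouds(self, rng):
        X = np.vstack([rng.normal(0, 0.1, size=(10, 2)),
                       rng.normal(8, 0.1, size=(10, 2))])
        truth = np.repeat([0, 1], 10)
        sol = cluster(X, "kmeans", 2, seed=1)
        assert adjusted_rand_score(truth, sol.labels) == 1.0

    @pytest.mark.parametrize("algo", ["kmeans", "ward", "pam", "diana"])
    def test_all_algorithms_agree_on_trivial_geometry(self, algo, rng):
        X = np.vstack([rng.normal(0, 0.05, size=(6, 3)),
                       rng.normal(5, 0.05, size=(6, 3))])
        sol = cluster(X, algo, 2, seed=0)
        assert adjusted_rand_score(np.repeat([0, 1], 6), sol.labels) == 1.0

    def test_diana_isolates_the_outlier(self):
        X = np.array([[0.0], [0.1], [10.0]])
        sol = cluster(X, "diana", 2)
        assert sol.labels[2] != sol.labels[0]
        assert sol.labels[0] == sol.labels[1]

    def test_k_equals_n_gives_singletons(self, rng):
        X = rng.normal(size=(5, 2))
        for algo in ("kmeans", "ward", "pam", "diana"):
            sol = cluster(X, algo, 5, seed=0)
            assert sorted(sol.labels) == [1, 2, 3, 4, 5]

    def test_k_above_n_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster(rng.normal(size=(4, 2)), "kmeans", 5)

    def test_labels_are_one_based_and_full(self, rng):
        X = rng.normal(size=(12, 3))
        for algo in ("kmeans", "ward", "pam", "diana"):
            sol = cluster(X, algo, 3, seed=0)
            assert set(sol.labels) == {1, 2, 3}

    def test_labels_stable_under_feature_permutation(self, rng):
        X = rng.normal(size=(10, 4))
        perm = rng.permutation(4)
        for algo in ("ward", "pam", "diana"):
            a = cluster(X, algo, 3).labels
            b = cluster(X[:, perm], algo, 3).labels
            assert adjusted_rand_score(a, b) == 1.0

    def test_kmeans_deterministic_given_seed(self, rng):
        X = rng.normal(size=(20, 3))
        a = cluster(X, "kmeans", 4, seed=7).labels
        b = cluster(X, "kmeans", 4, seed=7).labels
        np.testing.assert_array_equal(a, b)


def test_diana_matches_reference_implementation_on_tiny_instances():
    """Splinter-based divisive clustering vs R's cluster::diana, all k <= n <= 7."""
    rng = np.random.default_rng(99)
    for _ in range(8):
        n = int(rng.integers(4, 8))
        X = rng.normal(size=(n, 2)).round(4)
        flat = ",".join(str(v) for v in X.T.flatten())
        for k in range(2, n + 1):
            mine = cluster(X, "diana", k).labels
            code = (f"suppressMessages(library(cluster));"
                    f"X<-matrix(c({flat}),ncol=2);"
                    f"cat(cutree(as.hclust(diana(X,diss=FALSE)),k={k}))")
            out = subprocess.run(["Rscript", "-e", code],
                                 capture_output=True, text=True, check=True)
            ref = np.array([int(v) for v in out.stdout.split()])
            assert adjusted_rand_score(mine, ref) == 1.0


class TestValidation:
    def test_separated_clouds_zero_connectivity_high_dunn(self, rng):
        X = np.vstack([rng.normal(0, 0.1, size=(8, 2)),
                       rng.normal(10, 0.1, size=(8, 2))])
        sol = cluster(X, "kmeans", 2, seed=0)
        rep = validate_clusterings(X, [sol]).table.iloc[0]
        assert rep["connectivity"] == 0.0
        assert rep["dunn"] > 1.0
        assert rep["silhouette"] > 0.9

    def test_random_labels_near_zero_silhouette(self):
        sils = []
        for s in range(10):
            rng = np.random.default_rng(s)
            X = rng.normal(size=(40, 2))
            lab = rng.integers(1, 3, size=40)
            from soundscapemap.cluster import ClusterSolution
            sol = ClusterSolution("kmeans", 2, lab, [f"S{i}" for i in range(40)])
            rep = validate_clusterings(X, [sol]).table.iloc[0]
            sils.append(rep["silhouette"])
        assert max(abs(s) for s in sils) < 0.15

    def test_singleton_only_solution_flagged(self, rng):
        X = rng.normal(size=(4, 2))
        sol = cluster(X, "ward", 4)
        rep = validate_clusterings(X, [sol]).table.iloc[0]
        assert rep["silhouette"] == 0.0
        assert rep["silhouette_degenerate"]


class TestClassicalMDS:
    def test_exact_recovery_of_planar_configuration(self, rng):
        P = rng.normal(size=(10, 2))
        D = squareform(pdist(P))
        emb = classical_mds(D)
        D2 = squareform(pdist(emb.coordinates))
        np.testing.assert_allclose(D2, D, atol=1e-8)

    def test_collinear_points_have_null_second_axis(self):
        P = np.array([[0.0], [1.0], [2.5]])
        D = squareform(pdist(P))
        emb = classical_mds(D)
        assert abs(emb.eigenvalues[1]) < 1e-10

    def test_zero_distances_collapse_to_origin(self):
        emb = classical_mds(np.zeros((4, 4)))
        np.testing.assert_allclose(emb.coordinates, 0.0, atol=1e-12)

    def test_centred_output(self, rng):
        D = squareform(pdist(rng.normal(size=(8, 2))))
        emb = classical_mds(D)
        np.testing.assert_allclose(emb.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_asymmetric_input_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            classical_mds(D)
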