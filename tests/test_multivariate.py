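import itertools

import numpy as np
import pandas as pd
import pytest

import droughtscreen as ds
from droughtscreen.multivariate import dendrogram_newick, standardize


def matrix_from(arr, cols=None, regime="WD"):
    arr = np.asarray(arr, dtype=float)
    cols = cols or [f"t{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=[f"E{i}" for i in range(arr.shape[0])],
                      columns=cols)
    return ds.EcotypeTraitMatrix(data=df, water_regime=regime)


class TestCorrelationMatrix:
    def test_duplicated_and_negated_columns(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=8)
        m = matrix_from(np.column_stack([x, x, -x]))
        c = ds.correlation_matrix(m)
        assert c.r.iloc[0, 1] == pytest.approx(1.0)
        assert c.p.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert c.r.iloc[0, 2] == pytest.approx(-1.0)
        assert c.stars.iloc[0, 1] == "***"

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 3))
        c = ds.correlation_matrix(matrix_from(X))
        for i, j in itertools.combinations(range(3), 2):
            xi, xj = X[:, i], X[:, j]
            num = ((xi - xi.mean()) * (xj - xj.mean())).sum()
            den = np.sqrt(((xi - xi.mean()) ** 2).sum()
                          * ((xj - xj.mean()) ** 2).sum())
            assert c.r.iloc[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_too_few_rows_fatal(self):
        with pytest.raises(ValueError):
            ds.correlation_matrix(matrix_from(np.eye(2)))


class TestPca:
    def test_single_varying_column_gives_pc1_everything(self):
        X = np.column_stack([np.arange(6.0), np.arange(6.0) * 2])
        res = ds.pca(matrix_from(X))
        assert res.contributions["PC1"] == pytest.approx(100.0)

    def test_eigenvalues_match_eigendecomposition_oracle(self):
        """Explained variances equal the eigenvalues of the correlation
        matrix of the input (independent eigen oracle)."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            X = rng.normal(size=(10, 6))
            res = ds.pca(matrix_from(X))
            Z = (X - X.mean(0)) / X.std(0, ddof=1)
            ev = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)
                                            * 1.0))[::-1]
            # correct for ddof: corrcoef of z-scored data is the ddof=1
            # covariance, matching sklearn's explained_variance_
            assert np.max(np.abs(res.eigenvalues - ev)) < 1e-10

    def test_reconstruction_and_score_orthogonality(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 5))
        m = matrix_from(X)
        res = ds.pca(m)
        Z = standardize(m.data).to_numpy()
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.max(np.abs(recon - Z)) < 1e-8
        gram = res.scores.to_numpy().T @ res.scores.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8
        assert res.contributions.sum() == pytest.approx(100.0)

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(9, 4))
        r1, r2 = ds.pca(matrix_from(X)), ds.pca(matrix_from(X))
        pd.testing.assert_frame_equal(r1.scores, r2.scores)
        for col in r1.loadings:
            dom = r1.loadings[col].abs().idxmax()
            assert r1.loadings.loc[dom, col] > 0

    def test_zero_variance_column_fatal(self):
        X = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="t1"):
            ds.pca(matrix_from(X))


class TestRankingValues:
    def test_single_component_weighting(self):
        X = np.column_stack([np.arange(6.0), 3 * np.arange(6.0)])
        res = ds.pca(matrix_from(X))
        tab = ds.ranking_values(res, n_components=1)
        expected = 100.0 * res.scores["PC1"]
        assert np.allclose(tab["ranking_value"],
                           expected.loc[tab.index])

    def test_three_ecotype_hand_computation(self):
        rng = np.random.default_rng(11)
        res = ds.pca(matrix_from(rng.normal(size=(3, 3))))
        tab = ds.ranking_values(res, n_components=2)
        for eco in tab.index:
            hand = (res.contributions["PC1"] * res.scores.loc[eco, "PC1"]
                    + res.contributions["PC2"] * res.scores.loc[eco, "PC2"])
            assert tab.loc[eco, "ranking_value"] == pytest.approx(hand)

    def test_dense_rank_contract_on_any_pca(self):
        rng = np.random.default_rng(12)
        res = ds.pca(matrix_from(rng.normal(size=(10, 5))))
        tab = ds.ranking_values(res)
        assert sorted(tab["numerical_rank"]) == list(range(1, 11))
        assert (tab["ranking_value"].diff().dropna() <= 1e-12).all()

    def test_published_ranking_table_sorts_to_printed_ranks(self):
        t4 = ds.load_fixture("table4")
        by_value = t4.sort_values("ranking_value", ascending=False)
        assert by_value["numerical_rank"].tolist() == list(range(1, 36))
        assert by_value["ecotype"].iloc[0] == "K17"
        assert by_value["ecotype"].iloc[-1] == "K9"

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(8, 4))
        m1 = matrix_from(X)
        perm = rng.permutation(8)
        df2 = m1.data.iloc[perm]
        m2 = ds.EcotypeTraitMatrix(data=df2, water_regime="WD")
        t1 = ds.ranking_values(ds.pca(m1))
        t2 = ds.ranking_values(ds.pca(m2))
        assert t1["numerical_rank"].sort_index().equals(
            t2["numerical_rank"].sort_index())

    def test_too_many_components_fatal(self):
        res = ds.pca(matrix_from(np.random.default_rng(1).normal(size=(4, 3))))
        with pytest.raises(ValueError):
            ds.ranking_values(res, n_components=5)


def brute_force_average_linkage(X):
    """Exhaustive agglomeration oracle: repeatedly merge the pair of
    clusters with the smallest average pairwise Euclidean distance."""
    clusters = [[i] for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([np.linalg.norm(X[i] - X[j])
                         for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        d, a, b = best
        merges.append((sorted(clusters[a] + clusters[b]), d))
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return merges


class TestHierarchicalCluster:
    def test_identical_rows_merge_at_height_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 6.0], [7.0, 1.0]])
        res = ds.hierarchical_cluster(matrix_from(X), linkage="average", k=2)
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0)
        assert set(res.linkage_matrix[0, :2].astype(int)) == {0, 1}

    def test_average_linkage_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(5, 3))
        m = matrix_from(X)
        Z = ds.hierarchical_cluster(m, linkage="average", k=2).linkage_matrix
        Xs = standardize(m.data).to_numpy()
        oracle = brute_force_average_linkage(Xs)
        # compare merge heights (same agglomeration path)
        assert np.allclose(sorted(Z[:, 2]), sorted(h for _, h in oracle))

    def test_heights_monotone_nondecreasing(self, trial):
        obs, _ = trial
        mat = ds.to_matrix(ds.summarize(obs), "WD")
        for linkage in ("ward", "average", "complete"):
            Z = ds.hierarchical_cluster(mat, linkage=linkage, k=5).linkage_matrix
            assert (np.diff(Z[:, 2]) >= -1e-10).all()

    def test_k_equals_rows_gives_singletons(self):
        rng = np.random.default_rng(22)
        m = matrix_from(rng.normal(size=(6, 3)))
        res = ds.hierarchical_cluster(m, k=6)
        assert res.assignments.nunique() == 6
        prof = ds.cluster_profile(res, m)
        assert (prof["size"] == 1).all()
        assert (prof[[c for c in prof if c.endswith("_sem")]] == 0).all().all()

    def test_duplicate_labels_fatal(self):
        df = pd.DataFrame(np.random.default_rng(1).normal(size=(4, 3)),
                          index=["A", "A", "B", "C"])
        with pytest.raises(ValueError, match="duplicate"):
            ds.EcotypeTraitMatrix(data=df, water_regime="WD")

    def test_recovers_planted_classes_at_k3(self, trial):
        """Ward clustering of the default synthetic trial (seed 1) at k=3
        separates the planted tolerance classes (Rand index > 0.6)."""
        obs, truth = trial
        mat = ds.to_matrix(ds.summarize(obs), "WD")
        res = ds.hierarchical_cluster(mat, linkage="ward", k=3)
        labels = truth.classes.loc[res.ecotypes].to_numpy()
        pred = res.assignments.to_numpy()
        n = len(pred)
        agree = sum(
            (labels[i] == labels[j]) == (pred[i] == pred[j])
            for i, j in itertools.combinations(range(n), 2))
        rand = agree / (n * (n - 1) / 2)
        assert rand > 0.6

    def test_newick_export_is_parseable_and_complete(self):
        rng = np.random.default_rng(30)
        m = matrix_from(rng.normal(size=(5, 3)))
        res = ds.hierarchical_cluster(m, k=2)
        nwk = dendrogram_newick(res)
        assert nwk.endswith(";") and nwk.count(",") == 4
        for eco in m.ecotypes:
            assert eco in nwk


class TestClusterProfile:
    def test_published_cluster_shares(self):
        sizes = ds.load_fixture("cluster_sizes")["size"]
        shares = ds.cluster_shares(sizes)
        assert shares[0] == pytest.approx(8.6, abs=0.05)
        assert np.allclose(np.round(shares, 1),
                           [8.6, 28.6, 25.7, 22.9, 14.3])

    def test_single_cluster_covers_everything(self):
        rng = np.random.default_rng(31)
        m = matrix_from(rng.normal(size=(6, 3)))
        res = ds.hierarchical_cluster(m, k=1)
        prof = ds.cluster_profile(res, m)
        assert len(prof) == 1
        assert prof["pct_of_cohort"].iloc[0] == pytest.approx(100.0)

    def test_profile_means_on_original_scale(self, trial):
        obs, _ = trial
        mat = ds.to_matrix(ds.summarize(obs), "WD")
        res = ds.hierarchical_cluster(mat, k=4)
        prof = ds.cluster_profile(res, mat)
        assert prof["size"].sum() == len(mat.ecotypes)
        c = prof.index[0]
        members = res.assignments[res.assignments == c].index
        assert prof.loc[c, "PH_mean"] == pytest.approx(
            mat.data.loc[members, "PH"].mean())
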