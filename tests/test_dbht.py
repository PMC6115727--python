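import networkx as nx
import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import adjusted_rand_score

import subtypeflow as sf
from subtypeflow.dbht import sorted_candidate_edges

from ._oracles import pmfg_bruteforce


def random_similarity(N, seed):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((3 * N, N))
    return sf.pearson_similarity(X)


class TestPearson:
    def test_identical_columns_have_unit_correlation(self):
        X = np.tile(np.arange(5.0)[:, None], (1, 3)) + np.array([0.0, 1.0, 2.0])
        r = sf.pearson_similarity(X)
        assert np.allclose(r, 1.0)

    def test_reversed_column_has_minus_one(self):
        X = np.column_stack([(1.0, 2.0, 3.0), (3.0, 2.0, 1.0)])
        r = sf.pearson_similarity(X)
        assert r[0, 1] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        X = rng.standard_normal((10, 4))
        r = sf.pearson_similarity(X)
        for i in range(4):
            for j in range(4):
                xi, xj = X[:, i], X[:, j]
                num = np.sum((xi - xi.mean()) * (xj - xj.mean()))
                den = np.sqrt(np.sum((xi - xi.mean()) ** 2) * np.sum((xj - xj.mean()) ** 2))
                assert r[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_column_names_the_sample(self):
        X = np.column_stack([(1.0, 2.0, 3.0), (4.0, 4.0, 4.0)])
        with pytest.raises(sf.ZeroVarianceError, match="flatliner"):
            sf.pearson_similarity(X, sample_ids=["ok", "flatliner"])


class TestDissimilarity:
    @pytest.mark.parametrize("r,printed,sqrt", [
        (1.0, 0.0, 0.0),
        (-1.0, 4.0, 2.0),
        (0.0, 2.0, np.sqrt(2.0)),
    ])
    def test_transform_values(self, r, printed, sqrt):
        m = np.array([[1.0, r], [r, 1.0]])
        assert sf.dissimilarity(m)[0, 1] == pytest.approx(printed)
        assert sf.dissimilarity(m, mode="sqrt")[0, 1] == pytest.approx(sqrt)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            sf.dissimilarity(np.eye(2), mode="euclid")


class TestPMFG:
    def test_three_vertices_give_the_triangle(self):
        g = sf.build_pmfg(random_similarity(3, 0))
        assert g.number_of_edges() == 3

    def test_four_vertices_give_k4(self):
        g = sf.build_pmfg(random_similarity(4, 1))
        assert g.number_of_edges() == 6
        assert all(g.has_edge(i, j) for i in range(4) for j in range(i + 1, 4))

    @pytest.mark.parametrize("N", [5, 9, 14, 23])
    def test_edge_count_and_planarity(self, N):
        g = sf.build_pmfg(random_similarity(N, N))
        assert g.number_of_edges() == 3 * (N - 2)
        assert nx.check_planarity(g)[0]

    def test_invariant_under_monotone_similarity_transform(self):
        r = random_similarity(12, 5)
        g1 = sf.build_pmfg(r)
        g2 = sf.build_pmfg((r + 1.0) / 2.0)  # strictly increasing map
        assert set(g1.edges()) == set(g2.edges())

    @pytest.mark.parametrize("N,seed", [(5, 0), (6, 1), (7, 2), (8, 3)])
    def test_matches_minor_planarity_oracle(self, N, seed):
        r = random_similarity(N, 100 + seed)
        g = sf.build_pmfg(r)
        assert {tuple(sorted(e)) for e in g.edges()} == pmfg_bruteforce(r)

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValueError):
            sf.build_pmfg(np.eye(2))

    def test_candidate_edge_tie_break_is_lexicographic(self):
        r = np.full((4, 4), 0.5)
        np.fill_diagonal(r, 1.0)
        edges = sorted_candidate_edges(r)
        assert [(u, v) for u, v, _ in edges] == [
            (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


class TestDBHT:
    def test_two_planted_blocks_recovered_exactly(self):
        X, lab = sf.correlated_blocks([20, 20], 0.9, n_genes=100, seed=7)
        res = sf.cluster_samples(X)
        assert res.n_clusters == 2
        assert adjusted_rand_score(lab, res.labels) == 1.0

    def test_three_planted_blocks_recovered_exactly(self):
        X, lab = sf.correlated_blocks([20, 20, 20], 0.9, n_genes=100, seed=11)
        res = sf.cluster_samples(X)
        assert res.n_clusters == 3
        assert adjusted_rand_score(lab, res.labels) == 1.0

    def test_structureless_graph_is_one_cluster(self):
        r = np.full((4, 4), 0.5)
        np.fill_diagonal(r, 1.0)
        res = sf.dbht_cluster(sf.build_pmfg(r), sf.dissimilarity(r))
        assert res.n_clusters == 1
        assert np.all(res.labels == 1)

    def test_labels_cover_1_to_k_and_linkage_shape(self):
        X, _ = sf.correlated_blocks([15, 15], 0.85, seed=3)
        res = sf.cluster_samples(X)
        N = 30
        assert sorted(set(res.labels)) == list(range(1, res.n_clusters + 1))
        assert res.linkage.shape == (N - 1, 4)
        assert np.all(np.diff(res.linkage[:, 2]) >= -1e-9)

    def test_cutting_dendrogram_at_intercluster_level_reproduces_labels(self):
        X, _ = sf.correlated_blocks([12, 12, 12], 0.9, seed=9)
        res = sf.cluster_samples(X)
        cut = fcluster(res.linkage, t=res.cut_height - 1e-9, criterion="distance")
        assert adjusted_rand_score(cut, res.labels) == 1.0

    def test_output_invariant_under_vertex_relabelling(self):
        X, _ = sf.correlated_blocks([10, 10], 0.9, n_genes=80, seed=13)
        rng = np.random.default_rng(1)
        perm = rng.permutation(20)
        res1 = sf.cluster_samples(X)
        res2 = sf.cluster_samples(X[:, perm])
        assert adjusted_rand_score(res1.labels[perm], res2.labels) == 1.0

    def test_disconnected_graph_rejected(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)])
        with pytest.raises(ValueError):
            sf.dbht_cluster(g, np.zeros((6, 6)))

    def test_sqrt_mode_changes_heights_not_topology(self):
        X, _ = sf.correlated_blocks([10, 10], 0.9, seed=2)
        a = sf.cluster_samples(X, mode="printed")
        b = sf.cluster_samples(X, mode="sqrt")
        assert np.array_equal(a.labels, b.labels)
        assert not np.allclose(a.linkage[:, 2], b.linkage[:, 2])
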