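"""PCA, t-SNE, SNN graph, modularity clustering and marker detection."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score, silhouette_score

from otoconv import cluster as cl

from conftest import toy_dataset


# ---------------------------------------------------------------------------
# exhaustive-enumeration oracle for modularity (used here and by the
# acceptance suite); independent of the Louvain implementation
# ---------------------------------------------------------------------------

def all_partitions(items):
    if not items:
        yield []
        return
    head, *rest = items
    for part in all_partitions(rest):
        for i, block in enumerate(part):
            yield part[:i] + [[head] + block] + part[i + 1:]
        yield [[head]] + part


def brute_force_q(weights, labels):
    W = np.asarray(sp.csr_matrix(weights).todense(), dtype=float)
    two_m = W.sum()
    q = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        l_c = W[np.ix_(idx, idx)].sum() / 2.0
        d_c = W[idx].sum()
        q += 2.0 * l_c / two_m - (d_c / two_m) ** 2
    return q


def best_partition_q(weights):
    W = sp.csr_matrix(weights)
    n = W.shape[0]
    best = -np.inf
    for part in all_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for ci, block in enumerate(part):
            labels[block] = ci
        best = max(best, brute_force_q(W, labels))
    return best


def two_cliques_graph():
    """Two 3-cliques joined by one bridge edge, unit weights."""
    W = np.zeros((6, 6))
    for a, b in combinations(range(3), 2):
        W[a, b] = W[b, a] = 1.0
    for a, b in combinations(range(3, 6), 2):
        W[a, b] = W[b, a] = 1.0
    W[2, 3] = W[3, 2] = 1.0
    return sp.csr_matrix(W)


class TestPca:
    def test_rank_one_matrix_single_component(self):
        u = np.outer(np.arange(5, dtype=float), [1.0, 2.0, 3.0])
        scores, loadings, var = cl.pca_embed(u, 3)
        assert var[0] > 1e-8
        assert np.all(var[1:] < 1e-10)

    def test_two_by_two_identity_hand_computed(self):
        # centered identity has PC1 along (1,-1)/sqrt(2) with scores
        # +-sqrt(2)/2 and sample variance 1
        scores, loadings, var = cl.pca_embed(np.eye(2), 2)
        assert np.allclose(np.abs(scores[:, 0]), np.sqrt(2) / 2)
        assert np.allclose(var[0], 1.0)
        assert np.allclose(var[1], 0.0, atol=1e-12)

    def test_variance_sums_to_total(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 8))
        _, _, var = cl.pca_embed(X, 8)
        total = X.var(axis=0, ddof=1).sum()
        assert np.isclose(var.sum(), total)
        assert np.all(np.diff(var) <= 1e-10)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 10))
        scores, _, _ = cl.pca_embed(X, 5)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8


class TestTsne:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 5))
        a = cl.tsne_embed(X, perplexity=10, seed=3)
        b = cl.tsne_embed(X, perplexity=10, seed=3)
        assert np.array_equal(a, b)

    def test_two_blobs_separate(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (40, 5)),
                       rng.normal(12, 1, (40, 5))])
        labels = np.repeat([0, 1], 40)
        emb = cl.tsne_embed(X, perplexity=15, seed=0)
        assert silhouette_score(emb, labels) > 0.5

    def test_perplexity_too_high_rejected(self):
        with pytest.raises(ValueError, match="perplexity"):
            cl.tsne_embed(np.zeros((10, 2)), perplexity=5)


class TestSnnGraph:
    def test_k_max_gives_complete_unit_graph(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 3))
        g = cl.build_snn_graph(X, k=7, prune=0.0)
        W = g.weights.toarray()
        off = ~np.eye(8, dtype=bool)
        assert np.allclose(W[off], 1.0)
        assert np.allclose(np.diag(W), 0.0)

    def test_two_distant_pairs_k1(self):
        X = np.array([[0.0], [0.1], [100.0], [100.1]])
        g = cl.build_snn_graph(X, k=1, prune=0.0)
        W = g.weights.toarray()
        assert W[0, 1] == 1.0 and W[2, 3] == 1.0
        assert W[0, 2] == W[0, 3] == W[1, 2] == W[1, 3] == 0.0

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_weights_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 4))
        g = cl.build_snn_graph(X, k=5, prune=0.0)
        W = g.weights.toarray()
        assert np.allclose(W, W.T)
        assert W.min() >= 0.0 and W.max() <= 1.0
        assert np.allclose(np.diag(W), 0.0)


class TestModularity:
    def test_two_cliques_partition_and_q(self):
        # enumeration gives Q* = 5/14 = 0.3571 at the clique partition
        W = two_cliques_graph()
        labels, q = cl.cluster_modularity(cl.SnnGraph(W, k=1), seed=0)
        assert len(np.unique(labels)) == 2
        assert np.all(labels[:3] == labels[0])
        assert np.all(labels[3:] == labels[3])
        assert np.isclose(q, 5.0 / 14.0, atol=1e-12)

    def test_complete_graph_single_cluster(self):
        n = 6
        W = sp.csr_matrix(np.ones((n, n)) - np.eye(n))
        labels, q = cl.cluster_modularity(cl.SnnGraph(W, k=n - 1), seed=0)
        assert len(np.unique(labels)) == 1
        # any split of a complete graph has Q <= 0
        for split in range(1, n):
            lab = (np.arange(n) < split).astype(int)
            assert brute_force_q(W, lab) <= 1e-12

    def test_reported_q_equals_formula_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = rng.integers(5, 15)
            W = rng.uniform(0, 1, (n, n)) * (rng.uniform(0, 1, (n, n)) < 0.4)
            W = np.triu(W, 1)
            W = W + W.T
            if W.sum() == 0:
                continue
            g = cl.SnnGraph(sp.csr_matrix(W), k=3)
            labels, q = cl.cluster_modularity(g, seed=1)
            assert np.isclose(q, brute_force_q(W, labels), atol=1e-12)

    def test_disconnected_components_not_split(self):
        # two disjoint triangles: optimum groups each component whole
        W = np.zeros((6, 6))
        for a, b in combinations(range(3), 2):
            W[a, b] = W[b, a] = 1.0
        for a, b in combinations(range(3, 6), 2):
            W[a, b] = W[b, a] = 1.0
        labels, q = cl.cluster_modularity(cl.SnnGraph(sp.csr_matrix(W), k=1),
                                          seed=0)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert np.isclose(q, best_partition_q(W), atol=1e-12)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty|edgeless"):
            cl.cluster_modularity(cl.SnnGraph(sp.csr_matrix((4, 4)), k=1))


class TestMarkers:
    def _clustered_toy(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(5.0, size=(20, 60))
        counts[0, :30] = rng.poisson(40.0, 30)   # exclusive to cluster A
        counts[0, 30:] = 0
        labels = np.repeat(["A", "B"], 30)
        return toy_dataset(counts), labels

    def test_exclusive_gene_is_top_marker(self):
        ds, labels = self._clustered_toy()
        markers = cl.find_markers(ds, labels)
        top_a = markers[markers["cluster"] == "A"].iloc[0]
        assert top_a["gene"] == "g0"
        assert top_a["pct_out"] == 0.0

    def test_identical_clusters_have_no_markers(self):
        rng = np.random.default_rng(7)
        half = rng.poisson(5.0, size=(15, 25))
        counts = np.hstack([half, half])
        ds = toy_dataset(counts)
        labels = np.repeat(["A", "B"], 25)
        markers = cl.find_markers(ds, labels)
        assert (markers["FDR"] >= 0.05).all()

    def test_permuted_labels_yield_no_significant_markers(self):
        ds, labels = self._clustered_toy()
        rng = np.random.default_rng(8)
        n_sig = [
            (cl.find_markers(ds, rng.permutation(labels))["FDR"] < 0.05).sum()
            for _ in range(20)
        ]
        assert np.median(n_sig) == 0

    def test_fdr_monotone_with_p(self):
        ds, labels = self._clustered_toy()
        markers = cl.find_markers(ds, labels).sort_values("p")
        assert (np.diff(markers["FDR"]) >= -1e-12).all()


class TestCompositionAndMeans:
    def test_single_sample_single_cluster(self):
        ds = toy_dataset(np.ones((3, 5), dtype=int))
        comp = cl.cluster_composition(np.zeros(5, dtype=int), ds.cell_meta)
        assert comp.shape == (1, 1) and comp.iloc[0, 0] == 1.0

    def test_thirty_seventy_split(self):
        ds = toy_dataset(np.ones((3, 10), dtype=int))
        labels = np.array([0] * 3 + [1] * 7)
        comp = cl.cluster_composition(labels, ds.cell_meta)
        assert np.allclose(comp.loc["s1"].to_numpy(), [0.3, 0.7])

    def test_rows_sum_to_one(self, preprocessed):
        data, _ = preprocessed
        labels = data.cell_meta["true_population"].to_numpy()
        comp = cl.cluster_composition(labels, data.cell_meta)
        assert np.allclose(comp.sum(axis=1), 1.0)

    def test_replicate_composition_similar(self, preprocessed):
        data, _ = preprocessed
        labels = data.cell_meta["true_population"].to_numpy()
        comp = cl.cluster_composition(labels, data.cell_meta)
        for cond in data.cell_meta["condition"].unique():
            reps = comp[comp.index.str.startswith(cond)]
            if len(reps) == 2:
                assert (reps.iloc[0] - reps.iloc[1]).abs().max() < 0.1

    def test_cluster_means_match_brute_force(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(4.0, size=(6, 12))
        ds = toy_dataset(counts)
        labels = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2, 2])
        means = cl.summarize_cluster_means(ds, labels)
        log = np.log2(counts + 1.0)
        for clid in (0, 1, 2):
            expected = log[:, labels == clid].mean(axis=1)
            assert np.allclose(means.loc[clid].to_numpy(), expected)

    def test_min_max_scaling(self):
        counts = np.array([[0, 0, 10, 10], [5, 5, 5, 5]])
        ds = toy_dataset(counts)
        labels = np.array([0, 0, 1, 1])
        scaled = cl.summarize_cluster_means(ds, labels, scale=True)
        assert scaled.loc[0, "g0"] == 0.0 and scaled.loc[1, "g0"] == 1.0
        assert (scaled["g1"] == 0.0).all()  # constant gene maps to 0


class TestEndToEndClustering:
    def test_recovers_true_populations(self, preprocessed):
        data, hvg = preprocessed
        result = cl.run_clustering(data, genes=hvg, seed=1,
                                   compute_markers=False)
        ari = adjusted_rand_score(data.cell_meta["true_population"],
                                  result.labels)
        assert ari >= 0.9
        assert np.isclose(result.modularity,
                          brute_force_q(result.snn.weights,
                                        result.labels.to_numpy()),
                          atol=1e-10)

    def test_q_within_bounds(self, preprocessed):
        data, hvg = preprocessed
        result = cl.run_clustering(data, genes=hvg, seed=1,
                                   compute_markers=False)
        assert -0.5 <= result.modularity <= 1.0
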