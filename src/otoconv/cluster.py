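"""Dimensionality reduction, SNN-graph construction and modularity clustering.

The clustering route is PCA on log2(expected count + 1) -> shared
nearest-neighbor (SNN) graph with Jaccard edge weights -> Louvain-style
modularity maximization, followed by one-vs-rest Wilcoxon marker
detection, per-sample cluster composition and cluster-mean summaries.
A 2-D t-SNE embedding is computed for visualization only; no inference
depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from statsmodels.stats.multitest import multipletests

from .synthetic import UmiDataset

__all__ = [
    "SnnGraph",
    "ClusterResult",
    "pca_embed",
    "tsne_embed",
    "build_snn_graph",
    "cluster_modularity",
    "find_markers",
    "cluster_composition",
    "summarize_cluster_means",
    "run_clustering",
    "modularity_q",
    "louvain_communities",
]


# ---------------------------------------------------------------------------
# PCA and t-SNE
# ---------------------------------------------------------------------------

def log_expression_matrix(dataset: UmiDataset,
                          genes: pd.Index | None = None) -> np.ndarray:
    """Cells x genes matrix of log2(count + 1), optionally gene-subset."""
    if genes is None:
        return dataset.log2p1().T
    idx = dataset.gene_names.get_indexer(genes)
    if (idx < 0).any():
        missing = list(pd.Index(genes)[idx < 0])
        raise KeyError(f"genes absent from dataset: {missing[:5]}")
    return dataset.log2p1()[idx].T


def pca_embed(matrix: np.ndarray, n_components: int
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of an observations x features matrix after feature centering.

    Returns (scores, loadings, variance_explained); scores columns are
    orthogonal and variance_explained (the component variances) is
    non-increasing and, over all components, sums to the total feature
    variance.
    """
    matrix = np.asarray(matrix, dtype=float)
    n_components = min(int(n_components), *matrix.shape)
    pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
    scores = pca.fit_transform(matrix)
    return scores, pca.components_, pca.explained_variance_


def tsne_embed(pc_scores: np.ndarray, perplexity: float = 30.0,
               seed: int = 0) -> np.ndarray:
    """2-D t-SNE of PC scores; deterministic under the seed."""
    n = pc_scores.shape[0]
    if perplexity >= (n - 1) / 3:
        raise ValueError(f"perplexity {perplexity} too large for {n} cells")
    tsne = TSNE(n_components=2, perplexity=perplexity, init="pca",
                random_state=int(seed))
    return tsne.fit_transform(np.asarray(pc_scores, dtype=float))


# ---------------------------------------------------------------------------
# SNN graph
# ---------------------------------------------------------------------------

@dataclass
class SnnGraph:
    """Cell graph with Jaccard shared-nearest-neighbor edge weights.

    ``weights`` is a symmetric sparse matrix with zero diagonal;
    ``w_ij = |N(i) & N(j)| / |N(i) | N(j)|`` where ``N(i)`` is cell i
    plus its k nearest neighbors in PC space (Euclidean; distance ties
    broken toward the lower cell index).
    """

    weights: sp.csr_matrix
    k: int

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def build_snn_graph(pc_scores: np.ndarray, k: int = 20,
                    prune: float = 1 / 15) -> SnnGraph:
    """Build the SNN graph from PC scores.

    Edges with Jaccard weight below ``prune`` are dropped (set
    ``prune=0`` to keep every positive-weight edge).
    """
    X = np.asarray(pc_scores, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two cells")
    k = min(int(k), n - 1)
    d2 = np.square(X[:, None, :] - X[None, :, :]).sum(axis=2) if n <= 2048 else None
    if d2 is None:  # memory-light path for larger inputs
        from sklearn.metrics import pairwise_distances_chunked
        rows = []
        for chunk in pairwise_distances_chunked(X, metric="sqeuclidean"):
            rows.append(chunk)
        d2 = np.vstack(rows)
    order = np.argsort(d2, axis=1, kind="stable")  # self first (distance 0)
    hood = order[:, : k + 1]  # N(i) = {i} + k nearest neighbors
    member = np.zeros((n, n), dtype=bool)
    member[np.repeat(np.arange(n), k + 1), hood.ravel()] = True
    inter = member.astype(np.int32) @ member.T.astype(np.int32)
    union = 2 * (k + 1) - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        w = inter / union
    np.fill_diagonal(w, 0.0)
    w[w < prune] = 0.0
    w = np.maximum(w, w.T)  # symmetry is exact already; keep it explicit
    return SnnGraph(weights=sp.csr_matrix(w), k=k)


# ---------------------------------------------------------------------------
# Modularity: formula evaluation + deterministic Louvain
# ---------------------------------------------------------------------------

def modularity_q(weights: sp.spmatrix | np.ndarray, labels: np.ndarray) -> float:
    """Weighted modularity Q = sum_c [L_c/m - (d_c/2m)^2] of a partition.

    ``L_c`` is the total intra-community edge weight, ``d_c`` the total
    strength of the community's nodes, ``m`` the total edge weight.
    """
    W = sp.csr_matrix(weights).astype(float)
    labels = np.asarray(labels)
    strength = np.asarray(W.sum(axis=1)).ravel()
    two_m = strength.sum()
    if two_m == 0:
        raise ValueError("graph has no edges")
    q = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        sub = W[idx][:, idx]
        l_c = sub.sum() / 2.0
        d_c = strength[idx].sum()
        q += l_c / (two_m / 2.0) - (d_c / two_m) ** 2
    return float(q)


def _exact_modularity_partition(W: sp.csr_matrix) -> np.ndarray:
    """Globally optimal modularity partition by exhaustive enumeration of
    set partitions (restricted-growth strings); feasible for tiny graphs.
    The first optimum in canonical enumeration order is returned, so the
    result is deterministic."""
    n = W.shape[0]
    dense = np.asarray(W.todense(), dtype=float)
    best_q, best = -np.inf, np.zeros(n, dtype=int)
    labels = np.zeros(n, dtype=int)

    def recurse(i: int, n_groups: int) -> None:
        nonlocal best_q, best
        if i == n:
            q = modularity_q(dense, labels)
            if q > best_q + 1e-12:
                best_q, best = q, labels.copy()
            return
        for g in range(n_groups + 1):
            labels[i] = g
            recurse(i + 1, max(n_groups, g + 1))

    recurse(0, 0)
    return best


#: graphs up to this many nodes are partitioned by exact enumeration
EXACT_MODULARITY_MAX_NODES = 8


def louvain_communities(weights: sp.spmatrix | np.ndarray,
                        seed: int = 0) -> np.ndarray:
    """Modularity maximization: exact for tiny graphs, Louvain otherwise.

    Graphs with at most :data:`EXACT_MODULARITY_MAX_NODES` nodes are
    solved by exhaustive enumeration (the global optimum).  Larger graphs
    use Louvain local moving/aggregation with a seed-fixed node-visit
    order; ties in modularity gain are broken toward the lower community
    index, making the result fully deterministic for a given seed.
    """
    W = sp.csr_matrix(weights).astype(float)
    n = W.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    if n <= EXACT_MODULARITY_MAX_NODES:
        labels = _exact_modularity_partition(W)
        _, labels = np.unique(labels, return_inverse=True)
        first: dict[int, int] = {}
        out = np.empty_like(labels)
        for i, c in enumerate(labels):
            out[i] = first.setdefault(c, len(first))
        return out
    labels = np.arange(n)
    rng = np.random.default_rng([int(seed), 7])

    current = W
    node_map = np.arange(n)  # original node -> current super-node
    while True:
        comm, improved = _louvain_level(current, rng)
        labels = comm[node_map]
        if not improved:
            break
        current, node_map = _aggregate(current, comm), comm[node_map]
    # relabel by first occurrence for stable output
    _, labels = np.unique(labels, return_inverse=True)
    first = {}
    out = np.empty_like(labels)
    next_id = 0
    for i, c in enumerate(labels):
        if c not in first:
            first[c] = next_id
            next_id += 1
        out[i] = first[c]
    return out


def _louvain_level(W: sp.csr_matrix, rng: np.random.Generator
                   ) -> tuple[np.ndarray, bool]:
    n = W.shape[0]
    strength = np.asarray(W.sum(axis=1)).ravel()
    two_m = strength.sum()
    comm = np.arange(n)
    comm_tot = strength.copy()
    order = rng.permutation(n)
    improved_any = False
    indptr, indices, data = W.indptr, W.indices, W.data
    while True:
        moved = 0
        for i in order:
            ci = comm[i]
            comm_tot[ci] -= strength[i]
            # weight from i to each neighboring community
            nbr = indices[indptr[i]:indptr[i + 1]]
            wts = data[indptr[i]:indptr[i + 1]]
            links: dict[int, float] = {}
            for j, w in zip(nbr, wts):
                if j != i:
                    links[comm[j]] = links.get(comm[j], 0.0) + w
            links.setdefault(ci, 0.0)
            best_c, best_gain = ci, links[ci] - comm_tot[ci] * strength[i] / two_m
            for c in sorted(links):
                gain = links[c] - comm_tot[c] * strength[i] / two_m
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            comm[i] = best_c
            comm_tot[best_c] += strength[i]
            if best_c != ci:
                moved += 1
        if moved == 0:
            break
        improved_any = True
    _, comm = np.unique(comm, return_inverse=True)
    return comm, improved_any


def _aggregate(W: sp.csr_matrix, comm: np.ndarray) -> sp.csr_matrix:
    k = comm.max() + 1
    P = sp.csr_matrix((np.ones(len(comm)), (comm, np.arange(len(comm)))),
                      shape=(k, len(comm)))
    return sp.csr_matrix(P @ W @ P.T)


# ---------------------------------------------------------------------------
# Cluster result container and high-level routines
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Labels, modularity, embeddings and marker table of one clustering."""

    labels: pd.Series
    n_clusters: int
    modularity: float
    snn: SnnGraph
    pc_scores: np.ndarray | None = None
    embedding_2d: pd.DataFrame | None = None
    markers: pd.DataFrame | None = None
    composition: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)


def cluster_modularity(graph: SnnGraph, seed: int = 0) -> tuple[np.ndarray, float]:
    """Louvain labels plus the modularity Q of the returned partition."""
    if graph.n_nodes == 0 or graph.weights.nnz == 0:
        raise ValueError("cannot cluster an empty or edgeless graph")
    labels = louvain_communities(graph.weights, seed=seed)
    return labels, modularity_q(graph.weights, labels)


def find_markers(dataset: UmiDataset, labels: np.ndarray | pd.Series,
                 min_log2fc: float = 0.25, min_pct_in: float = 0.10
                 ) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker detection per cluster.

    Tests run on log2(expected count + 1).  Genes are reported when the
    cluster-vs-rest log2 fold change is >= ``min_log2fc`` and the gene is
    detected in >= ``min_pct_in`` of in-cluster cells; BH FDR is computed
    across all reported tests.
    """
    labels = np.asarray(labels)
    log = dataset.log2p1()
    detected = dataset.counts > 0
    rows = []
    for cl in pd.unique(labels):
        mask = labels == cl
        if mask.sum() < 2 or (~mask).sum() < 2:
            continue
        x_in, x_out = log[:, mask], log[:, ~mask]
        mean_in, mean_out = x_in.mean(axis=1), x_out.mean(axis=1)
        lfc = mean_in - mean_out
        pct_in = detected[:, mask].mean(axis=1)
        pct_out = detected[:, ~mask].mean(axis=1)
        keep = (lfc >= min_log2fc) & (pct_in >= min_pct_in)
        if not keep.any():
            continue
        res = stats.mannwhitneyu(x_in[keep], x_out[keep], axis=1,
                                 alternative="two-sided")
        for g, p, l, pi, po in zip(np.flatnonzero(keep), res.pvalue,
                                   lfc[keep], pct_in[keep], pct_out[keep]):
            rows.append({"gene": dataset.gene_names[g], "cluster": cl,
                         "log2FC": float(l), "p": float(p),
                         "pct_in": float(pi), "pct_out": float(po)})
    markers = pd.DataFrame(rows, columns=["gene", "cluster", "log2FC", "p",
                                          "pct_in", "pct_out"])
    if len(markers):
        markers["FDR"] = multipletests(markers["p"], method="fdr_bh")[1]
        markers = markers.sort_values(["cluster", "p"]).reset_index(drop=True)
    else:
        markers["FDR"] = pd.Series(dtype=float)
    return markers


def cluster_composition(labels: np.ndarray | pd.Series,
                        cell_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample cluster proportions (rows are samples and sum to 1)."""
    table = pd.crosstab(cell_meta["sample"], pd.Series(np.asarray(labels),
                                                       index=cell_meta.index,
                                                       name="cluster"))
    return table.div(table.sum(axis=1), axis=0)


def summarize_cluster_means(dataset: UmiDataset,
                            labels: np.ndarray | pd.Series,
                            gene_list: pd.Index | list[str] | None = None,
                            scale: bool = False) -> pd.DataFrame:
    """Cluster x gene mean of log2(count + 1); optional per-gene min-max.

    With ``scale=True`` each gene's means are mapped to [0, 1] (max -> 1,
    min -> 0; constant genes map to 0 everywhere).
    """
    labels = np.asarray(labels)
    if gene_list is None:
        gene_list = dataset.gene_names
    idx = dataset.gene_names.get_indexer(gene_list)
    if (idx < 0).any():
        raise KeyError("gene_list contains genes absent from the dataset")
    log = dataset.log2p1()[idx]
    out = pd.DataFrame(
        {cl: log[:, labels == cl].mean(axis=1) for cl in pd.unique(labels)},
        index=pd.Index(gene_list, name="gene")).T.sort_index()
    if scale:
        rng_ = out.max(axis=0) - out.min(axis=0)
        out = (out - out.min(axis=0)).div(rng_.replace(0, np.nan), axis=1).fillna(0.0)
    return out


def run_clustering(dataset: UmiDataset, n_pcs: int = 30, k: int = 20,
                   perplexity: float = 30.0, seed: int = 0,
                   genes: pd.Index | None = None,
                   compute_tsne: bool = False,
                   compute_markers: bool = True) -> ClusterResult:
    """PCA -> SNN -> Louvain on a (typically HVG-restricted) dataset."""
    X = log_expression_matrix(dataset, genes)
    scores, _, _ = pca_embed(X, n_pcs)
    graph = build_snn_graph(scores, k=k)
    labels, q = cluster_modularity(graph, seed=seed)
    result = ClusterResult(
        labels=pd.Series(labels, index=dataset.cell_ids, name="cluster"),
        n_clusters=int(labels.max()) + 1,
        modularity=q,
        snn=graph,
        pc_scores=scores,
        params={"n_pcs": n_pcs, "k": k, "seed": seed},
    )
    if compute_tsne:
        coords = tsne_embed(scores, perplexity=perplexity, seed=seed)
        result.embedding_2d = pd.DataFrame(coords, index=dataset.cell_ids,
                                           columns=["tsne1", "tsne2"])
    if compute_markers:
        result.markers = find_markers(dataset, labels)
    result.composition = cluster_composition(labels, dataset.cell_meta)
    return result
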