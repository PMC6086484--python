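"""Transcription-factor co-expression network over the conversion continuum.

TF genes that are detected in enough cells and variable enough are
connected by an edge wherever the squared Pearson correlation of their
log2(expected count + 1) profiles exceeds a threshold (R^2 > 0.25 by
default; the sign of r is kept on the edge).  Communities of the
resulting unweighted graph are found by the same modularity-maximization
engine used for cell clustering, and the top-degree node of each
community is reported as its hub.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cluster import louvain_communities, modularity_q
from .preprocess import read_gene_list
from .synthetic import UmiDataset

__all__ = [
    "TfNetwork",
    "filter_tf_genes",
    "correlation_network",
    "detect_communities",
    "build_tf_network",
]


@dataclass
class TfNetwork:
    """Nodes, thresholded correlation edges and modularity communities."""

    nodes: pd.DataFrame            # index gene; columns n_detected, variance
    edges: pd.DataFrame            # gene_i, gene_j, r, r2
    r2_threshold: float
    communities: pd.Series | None = None   # gene -> community id
    modularity: float | None = None
    hubs: pd.DataFrame | None = None       # community, gene, degree
    params: dict = field(default_factory=dict)

    def degree(self) -> pd.Series:
        deg = pd.Series(0, index=self.nodes.index, name="degree")
        for col in ("gene_i", "gene_j"):
            deg = deg.add(self.edges[col].value_counts(), fill_value=0)
        return deg.astype(int)

    def adjacency(self) -> sp.csr_matrix:
        """Unweighted symmetric adjacency over the node set."""
        n = len(self.nodes)
        pos = {g: i for i, g in enumerate(self.nodes.index)}
        rows = [pos[g] for g in self.edges["gene_i"]]
        cols = [pos[g] for g in self.edges["gene_j"]]
        data = np.ones(len(rows))
        A = sp.coo_matrix((data, (rows, cols)), shape=(n, n))
        A = A + A.T
        return sp.csr_matrix(A)


def filter_tf_genes(dataset: UmiDataset,
                    tf_list: Iterable[str] | str | Path,
                    min_cells_detected: int = 10,
                    min_variance: float = 0.4) -> pd.Index:
    """TF genes detected in >= ``min_cells_detected`` cells whose
    log2(count + 1) variance exceeds ``min_variance``.

    ``tf_list`` is an iterable of symbols or a one-symbol-per-line file;
    matching is case-insensitive.
    """
    symbols = read_gene_list(tf_list) if isinstance(tf_list, (str, Path)) else tf_list
    wanted = {s.lower() for s in symbols}
    is_tf = np.array([g.lower() in wanted for g in dataset.gene_names])
    detected = (dataset.counts > 0).sum(axis=1)
    var = dataset.log2p1().var(axis=1)
    keep = is_tf & (detected >= min_cells_detected) & (var > min_variance)
    return dataset.gene_names[keep]


def correlation_network(dataset: UmiDataset, nodes: Sequence[str],
                        r2_threshold: float = 0.25) -> TfNetwork:
    """All-pairs Pearson correlation with R^2 edge thresholding.

    Every node pair is scored on log2(count + 1); an (undirected,
    self-loop-free) edge is created iff r^2 > ``r2_threshold``, keeping
    the sign of r.
    """
    nodes = pd.Index(nodes)
    idx = dataset.gene_names.get_indexer(nodes)
    if (idx < 0).any():
        raise KeyError("network nodes missing from dataset")
    log = dataset.log2p1()[idx]
    detected = (dataset.counts[idx] > 0).sum(axis=1)
    var = log.var(axis=1)
    node_table = pd.DataFrame({"n_detected": detected, "variance": var},
                              index=nodes)

    with np.errstate(invalid="ignore"):
        r = np.corrcoef(log)
    r = np.nan_to_num(np.atleast_2d(r), nan=0.0)
    rows = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if r[i, j] ** 2 > r2_threshold:
                rows.append({"gene_i": nodes[i], "gene_j": nodes[j],
                             "r": float(r[i, j]), "r2": float(r[i, j] ** 2)})
    edges = pd.DataFrame(rows, columns=["gene_i", "gene_j", "r", "r2"])
    return TfNetwork(nodes=node_table, edges=edges, r2_threshold=r2_threshold)


def detect_communities(network: TfNetwork, seed: int = 0) -> TfNetwork:
    """Modularity communities and per-community hub nodes, in place.

    Runs the deterministic Louvain engine on the unweighted edge set;
    isolated nodes each form their own community.  Hubs are the
    top-degree nodes of each community (ties listed together).
    """
    A = network.adjacency()
    if A.nnz == 0:
        raise ValueError("network has no edges")
    labels = louvain_communities(A, seed=seed)
    network.communities = pd.Series(labels, index=network.nodes.index,
                                    name="community")
    network.modularity = modularity_q(A, labels)

    deg = network.degree()
    hub_rows = []
    for c in np.unique(labels):
        members = network.communities.index[network.communities == c]
        dmax = deg[members].max()
        for g in members[deg[members] == dmax]:
            hub_rows.append({"community": int(c), "gene": g,
                             "degree": int(deg[g])})
    network.hubs = pd.DataFrame(hub_rows)
    return network


def build_tf_network(dataset: UmiDataset, tf_list: Iterable[str] | str | Path,
                     cell_filter: np.ndarray | None = None,
                     r2_threshold: float = 0.25,
                     min_cells_detected: int = 10,
                     min_variance: float = 0.4,
                     seed: int = 0) -> TfNetwork:
    """Filter TFs, threshold correlations and detect communities.

    ``cell_filter`` restricts the analysis to a cell subset (boolean mask
    or integer positions), e.g. the SC/cHC/HC conversion continuum.
    """
    data = dataset if cell_filter is None else dataset.subset_cells(cell_filter)
    nodes = filter_tf_genes(data, tf_list, min_cells_detected, min_variance)
    if len(nodes) < 2:
        raise ValueError("fewer than two TF genes pass the expression filter")
    net = correlation_network(data, nodes, r2_threshold)
    net.params = {"r2_threshold": r2_threshold,
                  "min_cells_detected": min_cells_detected,
                  "min_variance": min_variance, "seed": seed}
    if len(net.edges):
        detect_communities(net, seed=seed)
    return net
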