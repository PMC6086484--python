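"""Principal-tree pseudotime along the SC-to-HC conversion continuum.

Cells are ordered by (1) selecting ordering genes on a mean/empirical-
dispersion filter, (2) fitting a principal tree — k-means centroids in PC
space joined by a minimum spanning tree, with every cell projected onto
its nearest tree edge — and (3) measuring geodesic distance along the
tree from the root (the SC1 state), normalized to pseudotime tau in
[0, 1].  Pseudotime-dependent genes are found with a likelihood-ratio
test of a 3-df natural cubic spline of log2(expected count + 1) on tau
against an intercept-only model (Gaussian working likelihood).  Gene
profiles can be summarized over 100 equal-width pseudotime bins, and the
module also quantifies the coupling of the Atoh1-HA transgene with
endogenous Atoh1 (Pearson R^2, between-cluster fold change).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .cluster import log_expression_matrix, pca_embed
from .synthetic import UmiDataset

__all__ = [
    "Trajectory",
    "PseudotimeTestResult",
    "select_ordering_genes",
    "fit_principal_tree",
    "assign_pseudotime",
    "test_pseudotime_dependence",
    "bin_pseudotime_profiles",
    "transgene_correlation",
    "natural_spline_basis",
]


# ---------------------------------------------------------------------------
# Ordering-gene selection
# ---------------------------------------------------------------------------

def select_ordering_genes(dataset: UmiDataset, min_mean: float = 0.1,
                          min_dispersion: float = 1.0,
                          lower_detection_limit: float = 0.5) -> pd.Index:
    """Genes with mean >= ``min_mean`` and empirical dispersion
    (variance / mean) >= ``min_dispersion`` on expected counts, after
    zeroing values below the detection limit."""
    x = dataset.counts.astype(float)
    x = np.where(x >= lower_detection_limit, x, 0.0)
    mean = x.mean(axis=1)
    var = x.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    keep = (mean >= min_mean) & (disp >= min_dispersion)
    return dataset.gene_names[keep]


# ---------------------------------------------------------------------------
# Principal tree
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """A centroid-MST principal tree with per-cell projections.

    ``centroids`` live in the PC space of the ordering genes; ``edges``
    are MST edges (u, v, length).  Every cell is projected onto the
    closest point of its nearest edge: ``cell_edge`` stores the edge
    index and ``cell_offset`` the position along it in [0, 1] from u.
    Pseudotime fields are filled by :func:`assign_pseudotime`.
    """

    ordering_genes: pd.Index
    centroids: np.ndarray
    edges: list[tuple[int, int, float]]
    cell_edge: np.ndarray
    cell_offset: np.ndarray
    pc_scores: np.ndarray
    cell_ids: pd.Index
    root_centroid: int | None = None
    pseudotime: pd.Series | None = None
    params: dict = field(default_factory=dict)

    def node_degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.centroids), dtype=int)
        for u, v, _ in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def branch_labels(self) -> pd.Series:
        """Tree-edge index each cell projects to (a coarse branch label)."""
        return pd.Series(self.cell_edge, index=self.cell_ids, name="branch")


def fit_principal_tree(dataset: UmiDataset, ordering_genes: pd.Index,
                       n_centroids: int = 25, n_pcs: int = 10,
                       seed: int = 0) -> Trajectory:
    """Fit the centroid-MST principal tree and project cells onto it."""
    if n_centroids < 2:
        raise ValueError("n_centroids must be >= 2")
    if dataset.n_cells < n_centroids:
        raise ValueError("fewer cells than centroids")
    X = log_expression_matrix(dataset, ordering_genes)
    scores, _, _ = pca_embed(X, min(n_pcs, X.shape[1]))
    km = KMeans(n_clusters=n_centroids, n_init=10, random_state=int(seed))
    km.fit(scores)
    cent = km.cluster_centers_

    d = np.sqrt(np.square(cent[:, None] - cent[None, :]).sum(axis=2))
    mst = minimum_spanning_tree(d).toarray()
    edges = [(int(u), int(v), float(mst[u, v]))
             for u, v in zip(*np.nonzero(mst))]

    cell_edge = np.empty(dataset.n_cells, dtype=int)
    cell_offset = np.empty(dataset.n_cells)
    seg_u = np.array([cent[u] for u, _, _ in edges])
    seg_v = np.array([cent[v] for _, v, _ in edges])
    seg = seg_v - seg_u
    seg_len2 = np.maximum(np.square(seg).sum(axis=1), 1e-12)
    for c in range(dataset.n_cells):
        diff = scores[c][None, :] - seg_u
        t = np.clip((diff * seg).sum(axis=1) / seg_len2, 0.0, 1.0)
        proj = seg_u + t[:, None] * seg
        dist2 = np.square(scores[c][None, :] - proj).sum(axis=1)
        e = int(np.argmin(dist2))
        cell_edge[c], cell_offset[c] = e, float(t[e])

    return Trajectory(ordering_genes=pd.Index(ordering_genes),
                      centroids=cent, edges=edges, cell_edge=cell_edge,
                      cell_offset=cell_offset, pc_scores=scores,
                      cell_ids=dataset.cell_ids,
                      params={"n_centroids": n_centroids, "n_pcs": n_pcs,
                              "seed": seed})


def assign_pseudotime(trajectory: Trajectory, root_cluster: str,
                      labels: pd.Series | np.ndarray) -> pd.Series:
    """Pseudotime = normalized geodesic tree distance from the root.

    The root centroid is the tree node closest (in PC space) to the mean
    position of the cells labeled ``root_cluster``; each projected cell's
    distance runs along tree edges through the nearer edge endpoint.
    The result is scaled to [0, 1] and stored on the trajectory.
    """
    labels = np.asarray(labels)
    mask = labels == root_cluster
    if not mask.any():
        raise ValueError(f"no cells labeled {root_cluster!r}")
    root_pos = trajectory.pc_scores[mask].mean(axis=0)
    root = int(np.argmin(np.square(trajectory.centroids - root_pos).sum(axis=1)))

    n = len(trajectory.centroids)
    A = sp.lil_matrix((n, n))
    for u, v, w in trajectory.edges:
        A[u, v] = A[v, u] = w
    node_dist = shortest_path(sp.csr_matrix(A), directed=False, indices=root)

    tau = np.empty(len(trajectory.cell_ids))
    for c, (e, t) in enumerate(zip(trajectory.cell_edge, trajectory.cell_offset)):
        u, v, w = trajectory.edges[e]
        tau[c] = min(node_dist[u] + t * w, node_dist[v] + (1.0 - t) * w)
    span = tau.max()
    if span > 0:
        tau = tau / span
    out = pd.Series(tau, index=trajectory.cell_ids, name="pseudotime")
    trajectory.root_centroid = root
    trajectory.pseudotime = out
    return out


# ---------------------------------------------------------------------------
# Pseudotime-dependence test
# ---------------------------------------------------------------------------

def natural_spline_basis(x: np.ndarray, df: int = 3) -> np.ndarray:
    """Natural cubic spline basis (no intercept column) with ``df`` terms.

    Boundary knots at min/max of x, ``df - 1`` interior knots at
    quantiles; linearity is enforced beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    probs = np.linspace(0, 1, df + 1)
    knots = np.quantile(x, probs)
    knots = np.unique(knots)
    if len(knots) < 3:  # degenerate spread: fall back to a linear term
        return (x - x.mean())[:, None]
    kK = knots[-1]

    def d(l_knot: float) -> np.ndarray:
        return (np.clip(x - l_knot, 0, None) ** 3
                - np.clip(x - kK, 0, None) ** 3) / (kK - l_knot)

    dKm1 = d(knots[-2])
    cols = [x] + [d(k) - dKm1 for k in knots[:-2]]
    return np.column_stack(cols)


@dataclass
class PseudotimeTestResult:
    """Per-gene spline LRT of expression on pseudotime."""

    table: pd.DataFrame  # columns: gene, lrt, df, p, FDR

    def significant(self, fdr: float = 0.05) -> pd.Index:
        t = self.table
        return pd.Index(t.loc[t["FDR"] < fdr, "gene"])


def test_pseudotime_dependence(dataset: UmiDataset,
                               tau: pd.Series | np.ndarray,
                               genes: pd.Index | None = None,
                               df: int = 3) -> PseudotimeTestResult:
    """Likelihood-ratio test of a natural-spline model of expression on tau.

    For each gene, log2(count + 1) is regressed on a ``df``-term natural
    cubic spline of pseudotime; the LRT statistic
    ``n * ln(RSS0 / RSS1)`` is referred to chi-square with ``df`` degrees
    of freedom (Gaussian working likelihood) and BH-adjusted across genes.
    """
    tau = np.asarray(tau, dtype=float)
    if genes is None:
        genes = dataset.gene_names
    Y = log_expression_matrix(dataset, genes)  # cells x genes
    n = Y.shape[0]
    B = natural_spline_basis(tau, df=df)
    X = np.column_stack([np.ones(n), B])
    k = B.shape[1]

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    rss1 = np.square(Y - X @ beta).sum(axis=0)
    rss0 = np.square(Y - Y.mean(axis=0)).sum(axis=0)
    rss1 = np.maximum(rss1, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        lrt = n * np.log(np.maximum(rss0, 1e-300) / rss1)
    constant = rss0 <= 1e-12
    lrt = np.where(constant, 0.0, lrt)
    p = stats.chi2.sf(lrt, k)
    p = np.where(constant, 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({"gene": pd.Index(genes), "lrt": lrt, "df": k,
                          "p": p, "FDR": fdr})
    return PseudotimeTestResult(table=table)


# ---------------------------------------------------------------------------
# Binned profiles and transgene correlation
# ---------------------------------------------------------------------------

def bin_pseudotime_profiles(dataset: UmiDataset, tau: pd.Series | np.ndarray,
                            genes: pd.Index | list[str] | None = None,
                            n_bins: int = 100,
                            scale: bool = False) -> pd.DataFrame:
    """Gene x bin matrix of mean log2(count + 1) over equal-width tau bins.

    Empty bins are filled by linear interpolation between neighboring
    non-empty bins; ``scale=True`` min-max scales each gene's profile.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    tau = np.asarray(tau, dtype=float)
    if genes is None:
        genes = dataset.gene_names
    log = log_expression_matrix(dataset, pd.Index(genes)).T  # genes x cells
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(tau, edges[1:-1]), 0, n_bins - 1)
    prof = np.full((log.shape[0], n_bins), np.nan)
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            prof[:, b] = log[:, mask].mean(axis=1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    filled = np.flatnonzero(~np.isnan(prof[0]))
    if len(filled) == 0:
        raise ValueError("no cells fall in any pseudotime bin")
    if len(filled) < n_bins:
        for g in range(prof.shape[0]):
            prof[g] = np.interp(centers, centers[filled], prof[g, filled])
    out = pd.DataFrame(prof, index=pd.Index(genes, name="gene"),
                       columns=[f"bin{b + 1}" for b in range(n_bins)])
    if scale:
        rng_ = out.max(axis=1) - out.min(axis=1)
        out = (out.sub(out.min(axis=1), axis=0)
               .div(rng_.replace(0, np.nan), axis=0).fillna(0.0))
    return out


def transgene_correlation(dataset: UmiDataset,
                          labels: pd.Series | np.ndarray,
                          fold_clusters: tuple[str, str] = ("cHC3", "cHC1")
                          ) -> dict:
    """Coupling of the Atoh1-HA transgene with endogenous Atoh1.

    Returns the squared Pearson correlation of log2(count + 1) between
    the two Atoh1 features over cells expressing either one, and the
    linear-scale fold change of Atoh1-HA between ``fold_clusters[0]`` and
    ``fold_clusters[1]`` cluster means.
    """
    labels = np.asarray(labels)
    gi_endo = dataset.gene_index(dataset.special_features["Atoh1_endogenous"])
    gi_ha = dataset.gene_index(dataset.special_features["Atoh1_HA"])
    expressing = (dataset.counts[gi_endo] > 0) | (dataset.counts[gi_ha] > 0)
    if expressing.sum() < 3:
        raise ValueError("too few cells express either Atoh1 feature")
    log = dataset.log2p1()
    r = np.corrcoef(log[gi_endo, expressing], log[gi_ha, expressing])[0, 1]

    hi, lo = fold_clusters
    ha = dataset.counts[gi_ha].astype(float)
    mean_hi = ha[labels == hi].mean() if (labels == hi).any() else np.nan
    mean_lo = ha[labels == lo].mean() if (labels == lo).any() else np.nan
    fold = mean_hi / mean_lo if mean_lo and np.isfinite(mean_lo) else np.nan
    return {"r2": float(r ** 2), "fold_change": float(fold),
            "n_cells": int(expressing.sum()),
            "fold_clusters": (hi, lo)}
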