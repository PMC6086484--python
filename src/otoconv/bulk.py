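"""Bulk RNA-seq normalization, differential expression and distances.

The route follows the standard edgeR/limma practice re-specified from
its published formulas: library normalization by the trimmed mean of
M-values (TMM), FPKM computation, precision-weighted linear models with
an empirical-Bayes moderated t statistic (the voom/eBayes approach:
lowess mean-variance trend, observation weights 1/trend^4, shrunken
residual variances), BH FDR per contrast, TF subsetting, replicate
concordance, and the six-metric cell-type distance suite (Spearman and
PC-space distances on several gene subsets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .preprocess import read_gene_list

__all__ = [
    "BulkExpressionSet",
    "DeResult",
    "tmm_factors",
    "compute_fpkm",
    "differential_expression",
    "subset_tf_de",
    "replicate_concordance",
    "distance_suite",
]


# ---------------------------------------------------------------------------
# Container
# ---------------------------------------------------------------------------

@dataclass
class BulkExpressionSet:
    """Counts, gene lengths and the sample -> cell-type map of one study.

    ``counts`` is genes x samples; ``sample_sheet`` is indexed by sample
    with a ``cell_type`` column.  ``min_cpm`` / ``min_samples`` define
    the low-expression trim applied before normalization and testing.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    sample_sheet: pd.DataFrame
    min_cpm: float = 1.0
    min_samples: int = 2
    _tmm: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(pd.Index(self.gene_lengths.index)):
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            raise ValueError("gene lengths missing for some genes")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        missing = set(self.counts.columns) - set(self.sample_sheet.index)
        if missing:
            raise ValueError(f"samples absent from sample sheet: {missing}")

    @classmethod
    def from_table(cls, table: pd.DataFrame, sample_sheet: pd.DataFrame,
                   **kw) -> "BulkExpressionSet":
        """Build from a (gene, length_bp, sample...) table as written by
        the bulk simulator."""
        table = table.set_index("gene")
        lengths = table["length_bp"]
        counts = table.drop(columns=["length_bp"])
        return cls(counts=counts, gene_lengths=lengths,
                   sample_sheet=sample_sheet, **kw)

    def trimmed(self) -> "BulkExpressionSet":
        """Drop genes below ``min_cpm`` counts-per-million in fewer than
        ``min_samples`` samples."""
        cpm = self.counts / self.counts.sum(axis=0) * 1e6
        keep = (cpm > self.min_cpm).sum(axis=1) >= self.min_samples
        return BulkExpressionSet(self.counts.loc[keep],
                                 self.gene_lengths.loc[keep],
                                 self.sample_sheet, self.min_cpm,
                                 self.min_samples)

    def tmm(self) -> pd.Series:
        if self._tmm is None:
            self._tmm = tmm_factors(self.counts)
        return self._tmm

    def cpm(self, prior_count: float = 0.5) -> pd.DataFrame:
        eff = self.counts.sum(axis=0) * self.tmm()
        return np.log2((self.counts + prior_count) / (eff + 1.0) * 1e6)

    def fpkm(self, normalized: bool = True) -> pd.DataFrame:
        out = compute_fpkm(self.counts, self.gene_lengths)
        if normalized:
            out = out / self.tmm()
        return out

    def cell_types(self) -> pd.Series:
        return self.sample_sheet.loc[self.counts.columns, "cell_type"]


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """Weighted trimmed mean of M-values of one sample against the
    reference; returns the (pre-rescaling) normalization factor."""
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok].astype(float), ref[ok].astype(float)
    if obs.size == 0:
        return 1.0
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    m_rank = stats.rankdata(m, method="average")
    a_rank = stats.rankdata(a, method="average")
    keep = ((m_rank >= n * trim_m + 1) & (m_rank <= n * (1 - trim_m))
            & (a_rank >= n * trim_a + 1) & (a_rank <= n * (1 - trim_a)))
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame | np.ndarray,
                lib_sizes: Sequence[float] | None = None,
                ref_sample: int | str | None = None,
                trim_m: float = 0.3, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    The 30% most extreme M (log expression ratio) and 5% most extreme A
    (log mean abundance) genes are trimmed; remaining M values are
    averaged with inverse-asymptotic-variance weights.  The reference is
    the sample whose upper-quartile CPM is closest to the mean upper
    quartile (unless given).  Factors are rescaled to geometric mean 1.
    """
    mat = np.asarray(counts, dtype=float)
    n_samples = mat.shape[1]
    names = (counts.columns if isinstance(counts, pd.DataFrame)
             else pd.RangeIndex(n_samples))
    lib = (np.asarray(lib_sizes, dtype=float) if lib_sizes is not None
           else mat.sum(axis=0))
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")

    if ref_sample is None:
        uq = np.array([np.quantile(mat[:, s] / lib[s], 0.75)
                       for s in range(n_samples)])
        ref = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref = (list(names).index(ref_sample) if isinstance(ref_sample, str)
               else int(ref_sample))

    f = np.array([
        1.0 if s == ref else _tmm_pair(mat[:, s], mat[:, ref], lib[s],
                                       lib[ref], trim_m, trim_a)
        for s in range(n_samples)
    ])
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=names, name="tmm_factor")


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series,
                 totals: pd.Series | None = None) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments:
    count / sample total * 1e6 / (length in kb)."""
    if totals is None:
        totals = counts.sum(axis=0)
    kb = lengths.reindex(counts.index) / 1000.0
    return counts.div(totals, axis=1).mul(1e6).div(kb, axis=0)


# ---------------------------------------------------------------------------
# voom-style differential expression with moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = special.polygamma(1, y)
        step = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + step
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment fit of a scaled F distribution to residual variances,
    returning (prior df d0, prior variance s0^2)."""
    s2 = np.maximum(s2, 1e-12)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0, s0 = np.inf, float(np.exp(emean))
    return float(d0), float(s0)


@dataclass
class DeResult:
    """Per-gene, per-contrast moderated-t differential expression."""

    table: pd.DataFrame            # gene, contrast, log2FC, t, p, FDR
    prior_df: float
    prior_var: float
    contrasts: tuple[str, ...]

    def significant(self, fdr: float = 0.05,
                    contrasts: Iterable[str] | None = None) -> pd.Index:
        t = self.table
        if contrasts is not None:
            t = t[t["contrast"].isin(set(contrasts))]
        return pd.Index(t.loc[t["FDR"] < fdr, "gene"].unique())


def differential_expression(eset: BulkExpressionSet,
                            contrasts: Sequence[tuple[str, str]] | None = None,
                            use_weights: bool = True,
                            trim: bool = True) -> DeResult:
    """Moderated-t DE between cell types on TMM-normalized log2-CPM.

    Per gene, a cell-type-means linear model is fitted by (optionally
    precision-weighted) least squares; the mean-variance trend is
    estimated by lowess of sqrt-residual-sd on average log2 count and
    inverted into observation weights (1/trend^4).  Residual variances
    are shrunk toward an empirical-Bayes prior and each contrast's
    log2 fold change is tested with the moderated t on ``d + d0``
    degrees of freedom, BH-adjusted within contrast.  With
    ``use_weights=False`` a plain moderated t without the trend weights
    is used.
    """
    if trim:
        eset = eset.trimmed()
    types = eset.cell_types()
    groups = list(pd.unique(types))
    counts_per_group = types.value_counts()
    if (counts_per_group < 2).any():
        bad = list(counts_per_group[counts_per_group < 2].index)
        raise ValueError(f"need >= 2 replicates per group; offending: {bad}")
    if contrasts is None:
        contrasts = list(combinations(groups, 2))

    y = eset.cpm().to_numpy()                      # genes x samples
    genes = eset.counts.index
    n_genes, n_samples = y.shape
    design = np.stack([(types == g).to_numpy().astype(float) for g in groups],
                      axis=1)                      # samples x groups
    df_resid = n_samples - len(groups)
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")

    eff_lib = eset.counts.sum(axis=0).to_numpy() * eset.tmm().to_numpy()

    def wls(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-gene weighted group means, residual variance and the
        variance factor of each group coefficient."""
        wsum = weights @ design                       # genes x groups
        beta = (weights * y) @ design / wsum
        fitted = beta @ design.T
        resid = y - fitted
        s2 = (weights * resid ** 2).sum(axis=1) / df_resid
        var_factor = 1.0 / wsum                       # Var(beta) = s2 * var_factor
        return beta, s2, var_factor

    if use_weights:
        beta0, s2_0, _ = wls(np.ones_like(y))
        mean_log_count = y.mean(axis=1) + np.log2(np.exp(np.mean(np.log(eff_lib + 1)))) - np.log2(1e6)
        sqrt_sd = np.sqrt(np.sqrt(np.maximum(s2_0, 1e-12)))
        order = np.argsort(mean_log_count)
        lo = lowess(sqrt_sd[order], mean_log_count[order], frac=0.5,
                    return_sorted=True)
        fitted_counts = (beta0 @ design.T
                         + np.log2(eff_lib + 1)[None, :] - np.log2(1e6))
        trend = np.interp(fitted_counts, lo[:, 0], lo[:, 1])
        weights = 1.0 / np.maximum(trend, 1e-4) ** 4
    else:
        weights = np.ones_like(y)

    beta, s2, var_factor = wls(weights)
    d0, s0 = _fit_f_dist(s2, df_resid)
    if np.isfinite(d0):
        s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0
    else:
        s2_post = np.full_like(s2, s0)
        df_total = np.inf

    group_pos = {g: i for i, g in enumerate(groups)}
    rows = []
    for a, b in contrasts:
        ia, ib = group_pos[a], group_pos[b]
        lfc = beta[:, ia] - beta[:, ib]
        se = np.sqrt(s2_post * (var_factor[:, ia] + var_factor[:, ib]))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, lfc / se, 0.0)
        if np.isfinite(df_total):
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        else:
            p = 2.0 * stats.norm.sf(np.abs(t))
        fdr = multipletests(p, method="fdr_bh")[1]
        name = f"{a}_vs_{b}"
        rows.append(pd.DataFrame({"gene": genes, "contrast": name,
                                  "log2FC": lfc, "t": t, "p": p, "FDR": fdr}))
    table = pd.concat(rows, ignore_index=True)
    return DeResult(table=table, prior_df=d0, prior_var=s0,
                    contrasts=tuple(f"{a}_vs_{b}" for a, b in contrasts))


def subset_tf_de(result: DeResult, tf_list: Iterable[str] | str | Path,
                 cell_types: Sequence[str] | None = None,
                 fdr: float = 0.05) -> pd.DataFrame:
    """TF genes significant (FDR < ``fdr``) in any pairwise contrast
    among ``cell_types`` (all contrasts when None)."""
    symbols = read_gene_list(tf_list) if isinstance(tf_list, (str, Path)) else tf_list
    wanted = {s.lower() for s in symbols}
    t = result.table
    if cell_types is not None:
        ok = [c for c in result.contrasts
              if all(part in cell_types for part in c.split("_vs_"))]
        t = t[t["contrast"].isin(ok)]
    sig = t[(t["FDR"] < fdr)
            & t["gene"].astype(str).str.lower().isin(wanted)]
    return (sig.sort_values(["gene", "contrast"])
            .reset_index(drop=True))


def replicate_concordance(eset: BulkExpressionSet,
                          on: str = "fpkm") -> pd.DataFrame:
    """Spearman correlation matrix across samples (unit diagonal)."""
    mat = eset.fpkm() if on == "fpkm" else eset.counts
    return mat.corr(method="spearman")


# ---------------------------------------------------------------------------
# Six-metric cell-type distance suite
# ---------------------------------------------------------------------------

def _pca_distance(profiles: pd.DataFrame, pairs: list[tuple[str, str]]
                  ) -> dict[tuple[str, str], float]:
    """Euclidean distance between cell types in the PC space of their
    mean profiles (all components kept)."""
    X = profiles.to_numpy().T                  # types x genes
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = u * s
    pos = {ct: i for i, ct in enumerate(profiles.columns)}
    return {p: float(np.linalg.norm(scores[pos[p[0]]] - scores[pos[p[1]]]))
            for p in pairs}


def distance_suite(eset: BulkExpressionSet, tf_list: Iterable[str] | str | Path,
                   cell_type_pairs: Sequence[tuple[str, str]] | None = None,
                   n_mad_genes: int = 200, fold_threshold: float = 4.0
                   ) -> pd.DataFrame:
    """Six distances per cell-type pair.

    ``spearman_all`` / ``spearman_tf``: 1 - Spearman rho of mean
    TMM-normalized FPKM profiles on all genes / the TF panel.
    ``pca_all`` / ``pca_tf`` / ``pca_mad`` / ``pca_4fold``: Euclidean
    distance in the PC space of log2(TMM-FPKM + 1) mean profiles on all
    genes, the TF panel, the ``n_mad_genes`` highest-MAD genes, and genes
    with >= ``fold_threshold``-fold change between some pair of cell
    types.  Genes with zero expression in every cell type are removed
    beforehand.
    """
    symbols = read_gene_list(tf_list) if isinstance(tf_list, (str, Path)) else tf_list
    wanted = {s.lower() for s in symbols}
    fpkm = eset.fpkm()
    types = eset.cell_types()
    prof = fpkm.T.groupby(types).mean().T        # genes x cell types
    prof = prof.loc[prof.sum(axis=1) > 0]
    log_prof = np.log2(prof + 1.0)

    cts = list(prof.columns)
    if cell_type_pairs is None:
        cell_type_pairs = list(combinations(cts, 2))
    pairs = [tuple(p) for p in cell_type_pairs]

    is_tf = prof.index.astype(str).str.lower().isin(wanted)
    mad = (log_prof.sub(log_prof.median(axis=1), axis=0)).abs().median(axis=1)
    top_mad = mad.sort_values(ascending=False).index[:n_mad_genes]
    ratio = (prof.max(axis=1) + 0.5) / (prof.min(axis=1) + 0.5)
    fold_genes = prof.index[ratio >= fold_threshold]

    out = {}
    for name, sub in (("spearman_all", prof), ("spearman_tf", prof.loc[is_tf])):
        rho = sub.corr(method="spearman")
        out[name] = {p: float(1.0 - rho.loc[p[0], p[1]]) for p in pairs}
    for name, sub in (("pca_all", log_prof), ("pca_tf", log_prof.loc[is_tf]),
                      ("pca_mad", log_prof.loc[top_mad]),
                      ("pca_4fold", log_prof.loc[fold_genes])):
        out[name] = _pca_distance(sub, pairs)

    table = pd.DataFrame(
        {metric: {f"{a}-{b}": v for (a, b), v in vals.items()}
         for metric, vals in out.items()})
    table.index.name = "pair"
    return table
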