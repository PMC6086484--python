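"""Single-cell multiplex qPCR quantification.

Calibration uses a threefold dilution series of 15 concentrations per
assay: the limit-of-detection threshold cycle (LOD-Ct) is the highest Ct
observed in the series, the universal LOD-Ct is the median of per-assay
LOD-Cts, and the amplification efficiency comes from the least-squares
slope of Ct on log10 relative concentration via
``efficiency = 10^(-1/slope) - 1``.  Chambers with multi-peak melt
curves (nonspecific amplification) are removed before quantification.
Cq values convert to expression as ``Log2(Ex) = LOD-Ct - Cq`` (clipped
at the detection floor of 0; chambers that never amplified sit at the
floor).  Group statistics use one-way ANOVA across cell types followed,
when significant, by pairwise t tests with Bonferroni correction, and
cross-platform concordance against bulk RNA-seq compares per-gene
log-ratios of group means between the two platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QpcrPlate",
    "CalibrationTable",
    "calibrate_lod",
    "melt_qc",
    "cq_to_expression",
    "group_compare",
    "cross_platform_concordance",
    "missingness_report",
]

logger = logging.getLogger(__name__)

PLATE_COLUMNS = ("assay", "chamber", "cell_id", "cell_type", "Cq", "melt_peaks")


@dataclass
class QpcrPlate:
    """Long-format plate: one row per (assay, chamber) with Cq
    (NaN = no amplification) and the number of melt-curve peaks."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(PLATE_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"plate table missing columns: {sorted(missing)}")
        cq = self.data["Cq"]
        if (cq.dropna() <= 0).any():
            raise ValueError("Cq values must be positive when present")
        peaks = self.data["melt_peaks"]
        if (peaks < 0).any() or (peaks != peaks.astype(int)).any():
            raise ValueError("melt_peaks must be non-negative integers")

    @property
    def assays(self) -> list[str]:
        return list(pd.unique(self.data["assay"]))


@dataclass
class CalibrationTable:
    """Per-assay LOD-Ct, standard-curve fit and efficiency.

    ``table`` columns: lod_ct (max Ct of the dilution series), slope,
    intercept (Ct vs log10 relative concentration), efficiency.
    ``universal_lod_ct`` is the median of the per-assay LOD-Cts.
    """

    table: pd.DataFrame
    universal_lod_ct: float

    def lod_ct(self, mode: str = "per_assay") -> pd.Series:
        if mode == "per_assay":
            return self.table["lod_ct"]
        if mode == "universal":
            return pd.Series(self.universal_lod_ct, index=self.table.index)
        raise ValueError("mode must be 'per_assay' or 'universal'")


def calibrate_lod(dilution_series: pd.DataFrame) -> CalibrationTable:
    """Fit the standard curve of each assay from its dilution series.

    ``dilution_series`` needs columns assay, relative_conc, Ct.  Per
    assay: LOD-Ct = max observed Ct; slope/intercept from least squares
    of Ct on log10(relative concentration); efficiency =
    10^(-1/slope) - 1 (so slope -3.3219 gives efficiency 1.0).
    """
    rows = {}
    for assay, grp in dilution_series.groupby("assay", sort=False):
        ct = grp["Ct"].to_numpy(dtype=float)
        conc = np.log10(grp["relative_conc"].to_numpy(dtype=float))
        fit = stats.linregress(conc, ct)
        eff = 10.0 ** (-1.0 / fit.slope) - 1.0 if fit.slope != 0 else np.nan
        rows[assay] = {"lod_ct": float(np.nanmax(ct)),
                       "slope": float(fit.slope),
                       "intercept": float(fit.intercept),
                       "efficiency": float(eff)}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "assay"
    return CalibrationTable(table=table,
                            universal_lod_ct=float(table["lod_ct"].median()))


def melt_qc(plate: QpcrPlate) -> QpcrPlate:
    """Remove chambers whose melt curve shows more than one peak."""
    bad = plate.data["melt_peaks"] > 1
    if bad.any():
        logger.info("melt-curve QC removed %d/%d chambers", int(bad.sum()),
                    len(plate.data))
    return QpcrPlate(plate.data.loc[~bad].reset_index(drop=True))


def cq_to_expression(plate: QpcrPlate, calibration: CalibrationTable,
                     lod_mode: str = "per_assay") -> pd.DataFrame:
    """Cells x assays matrix of Log2(Ex) = LOD-Ct - Cq.

    Missing Cq (a chamber that never amplified) and values below the
    floor map to 0.  Chambers absent from the plate (e.g. removed by
    melt-curve QC) are NaN, not 0: their expression is unknown, not
    undetected.  ``lod_mode`` selects the per-assay or the universal
    (plate-median) LOD-Ct.
    """
    lod = calibration.lod_ct(lod_mode)
    d = plate.data
    unknown = set(d["assay"]) - set(lod.index)
    if unknown:
        raise KeyError(f"assays without calibration: {sorted(unknown)}")
    ex = lod.reindex(d["assay"]).to_numpy() - d["Cq"].to_numpy(dtype=float)
    ex = np.clip(ex, 0.0, None)
    ex = np.where(np.isnan(ex), 0.0, ex)
    return (pd.DataFrame({"cell_id": d["cell_id"], "assay": d["assay"],
                          "log2_ex": ex})
            .pivot_table(index="cell_id", columns="assay", values="log2_ex",
                         aggfunc="mean"))


def group_compare(expression: pd.DataFrame, cell_types: pd.Series,
                  anova_alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA across cell types, then Bonferroni-corrected pairwise
    t tests for genes passing the ANOVA gate.

    Returns one row per gene with ``anova_F``, ``anova_p`` and, for each
    cell-type pair, ``p_<a>_vs_<b>`` columns (Bonferroni-adjusted over
    the number of pairs; NaN when the ANOVA is not significant at
    ``anova_alpha``).
    """
    cell_types = cell_types.reindex(expression.index)
    if cell_types.isna().any():
        raise ValueError("cell types missing for some cells")
    groups = list(pd.unique(cell_types))
    pairs = list(combinations(groups, 2))
    m = len(pairs)
    rows = []
    for assay in expression.columns:
        vals = [expression.loc[cell_types == g, assay].dropna().to_numpy()
                for g in groups]
        if any(len(v) < 2 for v in vals):
            raise ValueError("need >= 2 cells per group")
        if np.ptp(np.concatenate(vals)) == 0:
            f_stat, p = np.nan, 1.0
        else:
            f_stat, p = stats.f_oneway(*vals)
        row = {"gene": assay, "anova_F": float(f_stat) if np.isfinite(f_stat) else np.nan,
               "anova_p": float(p)}
        for (a, b) in pairs:
            key = f"p_{a}_vs_{b}"
            if p < anova_alpha:
                xa = expression.loc[cell_types == a, assay].dropna()
                xb = expression.loc[cell_types == b, assay].dropna()
                pt = stats.ttest_ind(xa, xb).pvalue
                row[key] = float(min(pt * m, 1.0))
            else:
                row[key] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def cross_platform_concordance(qpcr_expression: pd.DataFrame,
                               qpcr_cell_types: pd.Series,
                               bulk_fpkm: pd.DataFrame,
                               bulk_cell_types: pd.Series,
                               pairs: list[tuple[str, str]] | None = None,
                               type_map: dict[str, str] | None = None
                               ) -> pd.DataFrame:
    """Per-pair Pearson r^2 of per-gene log-ratios across the platforms.

    For each cell-type pair (a, b), the log2 ratio of group means is
    computed per shared gene on each platform (qPCR: mean Log2(Ex)
    difference; bulk: log2 ratio of mean FPKM + 0.5) and correlated
    across genes; the regression line of bulk on qPCR is reported.
    ``type_map`` translates qPCR cell-type names to bulk ones.
    """
    if pairs is None:
        pairs = [("cHC", "SC"), ("OHC", "cHC")]
    type_map = type_map or {}
    shared = qpcr_expression.columns.intersection(bulk_fpkm.index)
    if len(shared) < 3:
        raise ValueError("fewer than three genes shared between platforms")

    qpcr_cell_types = qpcr_cell_types.reindex(qpcr_expression.index)
    rows = []
    for a, b in pairs:
        qa = qpcr_expression.loc[qpcr_cell_types == a, shared].mean()
        qb = qpcr_expression.loc[qpcr_cell_types == b, shared].mean()
        q_ratio = qa - qb                      # Log2(Ex) is already log scale
        ba_cols = bulk_cell_types[bulk_cell_types == type_map.get(a, a)].index
        bb_cols = bulk_cell_types[bulk_cell_types == type_map.get(b, b)].index
        if len(ba_cols) == 0 or len(bb_cols) == 0:
            raise KeyError(f"bulk samples not found for pair ({a}, {b})")
        b_ratio = (np.log2(bulk_fpkm.loc[shared, ba_cols].mean(axis=1) + 0.5)
                   - np.log2(bulk_fpkm.loc[shared, bb_cols].mean(axis=1) + 0.5))
        fit = stats.linregress(q_ratio.to_numpy(), b_ratio.to_numpy())
        rows.append({"pair": f"{a}_vs_{b}", "r2": float(fit.rvalue ** 2),
                     "slope": float(fit.slope),
                     "intercept": float(fit.intercept),
                     "n_genes": int(len(shared))})
    return pd.DataFrame(rows).set_index("pair")


def missingness_report(plate: QpcrPlate) -> pd.DataFrame:
    """Per-assay count and fraction of chambers with no amplification
    (generalizes ad-hoc handling of assays with failed chambers)."""
    d = plate.data
    grp = d.groupby("assay")["Cq"]
    out = pd.DataFrame({"n_chambers": grp.size(),
                        "n_missing": grp.apply(lambda s: int(s.isna().sum()))})
    out["fraction_missing"] = out["n_missing"] / out["n_chambers"]
    return out
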