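"""Single-cell QC and depth harmonization.

Order of operations mirrors the analysis this package implements:
per-sample library-size filtering (doublet / low-quality removal),
binomial downsampling of every cell to the minimum retained library size
("expected counts", which removes depth as a batch covariate), removal of
blacklisted gene families (cell-cycle, apoptosis, ribosomal-protein
genes), and mean-dispersion highly-variable-gene (HVG) selection on
log2(expected count + 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import UmiDataset

__all__ = [
    "PreprocessParams",
    "DownsampledDataset",
    "filter_cells_by_library_size",
    "downsample_to_reference_depth",
    "remove_blacklisted_genes",
    "select_hvg",
    "filter_cells_by_metadata",
    "read_gene_list",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessParams:
    """Tunables of the QC stage.

    Library-size quantile cutoffs are applied within each sample
    separately.  ``hvg_n_bins`` equal-frequency mean-expression bins are
    used to z-score gene dispersion; genes with within-bin dispersion
    z-score >= ``hvg_dispersion_z_min`` are called highly variable.
    """

    lib_size_low_quantile: float = 0.02
    lib_size_high_quantile: float = 0.98
    blacklist_files: tuple[str, ...] = ()
    hvg_n_bins: int = 20
    hvg_dispersion_z_min: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lib_size_low_quantile < self.lib_size_high_quantile <= 1.0:
            raise ValueError("require 0 <= low < high <= 1 for library-size quantiles")
        if self.hvg_n_bins < 1:
            raise ValueError("hvg_n_bins must be >= 1")


@dataclass
class DownsampledDataset:
    """A depth-harmonized dataset plus provenance of what was removed."""

    dataset: UmiDataset
    reference_depth: int
    removed_cells: pd.Index = field(default_factory=lambda: pd.Index([]))
    removed_genes: pd.Index = field(default_factory=lambda: pd.Index([]))


def filter_cells_by_library_size(dataset: UmiDataset,
                                 params: PreprocessParams) -> UmiDataset:
    """Drop cells with extreme total UMI, separately within each sample.

    A cell is kept when its total lies inside the closed interval spanned
    by the sample-level [low, high] quantiles of totals (linear
    interpolation).  Raises if any sample would lose all its cells.  The
    total used is the recorded per-cell library size (``lib_size`` in the
    metadata) when available — sequencing depth is a property of the
    cell, so gene removal does not alter the filter — else the current
    count total.
    """
    if "lib_size" in dataset.cell_meta.columns:
        totals = dataset.cell_meta["lib_size"].to_numpy()
    else:
        totals = dataset.cell_totals()
    samples = dataset.cell_meta["sample"].to_numpy()
    keep = np.zeros(dataset.n_cells, dtype=bool)
    for sample in pd.unique(samples):
        mask = samples == sample
        lo, hi = np.quantile(totals[mask],
                             [params.lib_size_low_quantile,
                              params.lib_size_high_quantile])
        ok = mask & (totals >= lo) & (totals <= hi)
        if not ok.any():
            raise ValueError(f"library-size filter removed every cell of sample {sample!r}")
        keep |= ok
    removed = dataset.cell_ids[~keep]
    if len(removed):
        logger.info("library-size filter removed %d/%d cells", len(removed),
                    dataset.n_cells)
    return dataset.subset_cells(keep)


def filter_cells_by_metadata(dataset: UmiDataset, column: str,
                             allowed: Iterable[str]) -> UmiDataset:
    """Keep cells whose metadata ``column`` is in ``allowed``.

    Stands in for upstream label-based filters (e.g. keeping G1-phase
    cells when a cycle-phase label is provided in the metadata).
    """
    allowed = set(allowed)
    keep = dataset.cell_meta[column].isin(allowed).to_numpy()
    return dataset.subset_cells(keep)


def downsample_to_reference_depth(dataset: UmiDataset,
                                  seed: int = 0) -> DownsampledDataset:
    """Binomially downsample every cell to the minimum library size.

    For a cell with total ``T_c`` and gene counts ``x_gc``, the expected
    count is drawn as ``Binomial(n = min_c T_c, p = x_gc / T_c)``
    independently per gene, so zero counts stay zero and the expected new
    total equals the reference depth for every cell.  Independent
    binomials need not sum exactly to the reference; this matches the
    per-gene formulation (see docs for the exact multinomial alternative).
    """
    totals = dataset.cell_totals()
    if np.any(totals <= 0):
        raise ValueError("all cell totals must be > 0 before downsampling")
    ref = int(totals.min())
    rng = np.random.default_rng([int(seed), 100])
    p = dataset.counts / totals[None, :]
    new_counts = rng.binomial(ref, p)
    out = UmiDataset(new_counts, dataset.gene_names, dataset.cell_ids,
                     dataset.cell_meta, dict(dataset.special_features),
                     dataset.truth)
    return DownsampledDataset(dataset=out, reference_depth=ref)


def downsample_multinomial(dataset: UmiDataset, seed: int = 0) -> DownsampledDataset:
    """Multinomial variant: each cell's new counts sum exactly to the
    reference depth (sampling reads without replacement of composition)."""
    totals = dataset.cell_totals()
    if np.any(totals <= 0):
        raise ValueError("all cell totals must be > 0 before downsampling")
    ref = int(totals.min())
    rng = np.random.default_rng([int(seed), 101])
    new_counts = np.empty_like(dataset.counts)
    for c in range(dataset.n_cells):
        new_counts[:, c] = rng.multinomial(ref, dataset.counts[:, c] / totals[c])
    out = UmiDataset(new_counts, dataset.gene_names, dataset.cell_ids,
                     dataset.cell_meta, dict(dataset.special_features),
                     dataset.truth)
    return DownsampledDataset(dataset=out, reference_depth=ref)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list (blank lines, '#' comments ok)."""
    out = []
    for line in Path(path).read_text().splitlines():
        sym = line.strip()
        if sym and not sym.startswith("#"):
            out.append(sym)
    return out


def remove_blacklisted_genes(dataset: UmiDataset,
                             blacklists: Sequence[Iterable[str] | str | Path]
                             ) -> UmiDataset:
    """Remove genes matching any blacklist (case-insensitive exact symbol).

    Each entry of ``blacklists`` is either an iterable of symbols or a
    path to a one-symbol-per-line file.
    """
    banned: set[str] = set()
    for bl in blacklists:
        symbols = read_gene_list(bl) if isinstance(bl, (str, Path)) else bl
        banned.update(s.lower() for s in symbols)
    if not banned:
        return dataset
    lower = np.array([g.lower() for g in dataset.gene_names])
    keep = ~np.isin(lower, list(banned))
    if keep.all():
        warnings.warn("blacklists did not match any gene in the dataset",
                      stacklevel=2)
        return dataset
    logger.info("blacklist removed %d genes", (~keep).sum())
    return dataset.subset_genes(keep)


def select_hvg(dataset: UmiDataset, params: PreprocessParams
               ) -> tuple[pd.Index, pd.DataFrame]:
    """Mean-dispersion highly-variable-gene selection.

    On log2(expected count + 1) values, per-gene dispersion is
    variance / mean.  Genes are placed into ``hvg_n_bins`` equal-frequency
    bins of mean expression; the dispersion is z-scored within each bin
    and genes with z >= ``hvg_dispersion_z_min`` are selected.  Bins
    holding fewer than two genes are merged into their lower neighbor.
    Genes with zero mean are never selected.

    Returns ``(selected gene index, per-gene table)`` with columns
    ``mean``, ``dispersion``, ``bin``, ``z``, ``selected``.
    """
    log = dataset.log2p1()
    mean = log.mean(axis=1)
    var = log.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), np.nan)

    table = pd.DataFrame({"mean": mean, "dispersion": disp},
                         index=dataset.gene_names)
    nonzero = table["mean"] > 0
    if nonzero.sum() < params.hvg_n_bins:
        raise ValueError("fewer nonzero-mean genes than hvg_n_bins")

    ranks = table.loc[nonzero, "mean"].rank(method="first")
    bins = np.ceil(ranks / len(ranks) * params.hvg_n_bins).astype(int)
    # merge undersized bins into neighbors so every bin has >= 2 genes
    sizes = bins.value_counts().sort_index()
    relabel: dict[int, int] = {}
    group: list[int] = []
    group_size = 0
    group_id = 0
    for b in sizes.index:
        group.append(b)
        group_size += int(sizes[b])
        if group_size >= 2:
            for bb in group:
                relabel[bb] = group_id
            group_id, group, group_size = group_id + 1, [], 0
    for bb in group:  # trailing undersized bin joins the previous group
        relabel[bb] = max(group_id - 1, 0)
    if len(set(relabel.values())) < len(sizes):
        logger.warning("merged undersized HVG mean bins")
    bins = bins.map(relabel)

    table["bin"] = np.nan
    table.loc[nonzero, "bin"] = bins
    z = np.full(len(table), np.nan)
    for b, idx in table.loc[nonzero].groupby("bin").groups.items():
        d = table.loc[idx, "dispersion"].to_numpy()
        sd = d.std()
        z_bin = (d - d.mean()) / sd if sd > 0 else np.zeros_like(d)
        z[table.index.get_indexer(idx)] = z_bin
    table["z"] = z
    table["selected"] = nonzero & (table["z"] >= params.hvg_dispersion_z_min)
    selected = table.index[table["selected"]]
    return selected, table
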