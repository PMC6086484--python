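"""Synthetic data generators for the cochlear conversion pipeline.

Every downstream stage of the package (QC/downsampling, clustering,
pseudotime, TF networks, bulk DE, single-cell qPCR, conversion-rate
statistics) can be exercised on data produced here.  The generators emulate
the statistical structure of transcriptomic profiling of the organ of Corti
during Atoh1-mediated supporting-cell (SC) to hair-cell (HC) conversion:

* a gene x cell UMI count matrix with ~7 cell populations (SC1, SC2,
  cHC1-3, OHC, IHC), population-specific marker programs, a latent
  conversion coordinate ``s`` shared by the continuum populations
  SC1 -> cHC1 -> cHC2 -> cHC3, two transgene features (Atoh1-HA, tdTomato)
  and endogenous Atoh1 whose log2 expression is driven by ``s``;
* bulk RNA-seq count tables with biological duplicates for five isolated
  cell types (SC P26, cHC P33, OHC P7, OHC P22, IHC P74) and gene lengths;
* single-cell qPCR plates (Cq values with an efficiency/limit-of-detection
  model, melt-curve peak counts) plus a threefold 15-point dilution series;
* imaging cell-count tables for conversion-rate statistics.

UMI counts follow a negative binomial with variance ``mu + mu^2/theta``
(``theta`` = inverse dispersion), the standard droplet UMI noise model.
All generators are deterministic given a seed; each artifact type draws
from its own child stream of the master seed so artifacts are
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "UmiDataset",
    "BulkSimTruth",
    "QpcrSimTruth",
    "gen_umi_dataset",
    "gen_bulk_dataset",
    "gen_qpcr_plate",
    "gen_count_table",
    "default_sim_config",
    "continuum_sim_config",
    "default_bulk_truth",
    "default_qpcr_truth",
    "DEFAULT_POPULATIONS",
    "CONTINUUM_POPULATIONS",
    "ATOH1_ENDOGENOUS",
    "ATOH1_HA",
    "TDTOMATO",
]

# ---------------------------------------------------------------------------
# Naming conventions
# ---------------------------------------------------------------------------

ATOH1_ENDOGENOUS = "Atoh1"  # endogenous locus, counted through the 3'UTR
ATOH1_HA = "Atoh1-HA"       # CAG-driven transgene, counted through the HA tag
TDTOMATO = "tdTomato"       # Cre reporter marking the SC-derived lineage

DEFAULT_POPULATIONS = ("SC1", "SC2", "cHC1", "cHC2", "cHC3", "OHC", "IHC")
CONTINUUM_POPULATIONS = ("SC1", "cHC1", "cHC2", "cHC3")

# condition each population is predominantly sampled from; SC-lineage
# populations carry the tdTomato reporter
_POPULATION_CONDITION = {
    "SC1": "Coch_P12",
    "SC2": "Coch_P33",
    "cHC1": "Coch_Tmx_P26",
    "cHC2": "Coch_Tmx_P26",
    "cHC3": "Coch_Tmx_P33",
    "OHC": "Coch_P12",
    "IHC": "Coch_P33",
}
_SC_LINEAGE = {"SC1", "SC2", "cHC1", "cHC2", "cHC3"}

# TF stand-ins that rise along the conversion coordinate (co-driven with
# Atoh1, giving the Atoh1-centred co-expression module) and TFs of the
# departing SC program that fall along it.
_RISING_TFS = ("Barhl1", "Lhx3", "Gata3", "Hes6", "Neurod6", "Pou4f3",
               "Insm1", "Egr1", "Jund")
_FALLING_TFS = ("Rorb", "Rora", "Id1", "Id2", "Id4", "Hes5", "Hes1",
                "Sox9", "Zbtb20", "Fos", "Junb", "Jun")

# identity markers given recognizable symbols (first entries of each
# population's marker block); the remainder of each block uses generic names
_NAMED_MARKERS = {
    "SC1": ("Fgfr3", "Sfrp1"),
    "SC2": ("Gjb2", "Cdkn1b"),
    "cHC1": ("Ccnd1",),
    "cHC2": ("Rasd2",),
    "cHC3": ("Chrna10", "Chrna9", "Myo6", "Pvalb"),
    "OHC": ("Slc26a5", "Ocm", "Ikzf2", "Sall1", "Isl1"),
    "IHC": ("Slc17a8", "Otof"),
}

#: symbols treated as transcription factors by default presets
DEFAULT_TF_GENES = tuple(sorted(set(
    (ATOH1_ENDOGENOUS, ATOH1_HA) + _RISING_TFS + _FALLING_TFS
    + ("Isl1", "Ikzf2", "Sall1", "Cdkn1b")
)))


# ---------------------------------------------------------------------------
# Configuration and container types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Parameters of the single-cell UMI generator.

    ``cells_per_population`` may be a single count applied to every
    population or a mapping population -> count (0 removes a population).
    ``latent_loading_*`` are slopes of log2 mean expression of the two
    Atoh1 features on the latent conversion coordinate ``s in [0, 1]``;
    ``latent_noise_sd`` is the cell-level Gaussian noise of those log2
    means.  ``library_size_lognormal`` gives (mu, sigma) of the natural-log
    normal distribution of per-cell total UMI.
    """

    n_populations: int = 7
    cells_per_population: int | Mapping[str, int] = 100
    n_genes: int = 1000
    n_marker_genes_per_population: int = 20
    population_names: Sequence[str] = DEFAULT_POPULATIONS
    continuum_populations: Sequence[str] = CONTINUUM_POPULATIONS
    latent_loading_endoAtoh1: float = 3.4
    latent_loading_Atoh1HA: float = 3.4
    latent_noise_sd: float = 0.25
    library_size_lognormal: tuple[float, float] = (8.5, 0.35)
    nb_dispersion: float = 2.0
    transgene_dispersion: float = 50.0
    program_dispersion: float = 8.0
    marker_log2_boost: float = 3.0
    n_gradient_genes: int = 60
    gradient_log2_loading: float = 3.0
    batch_labels: Sequence[str] = ("rep1", "rep2")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1 or self.n_genes < 1:
            raise ValueError("n_populations and n_genes must be >= 1")
        if len(self.population_names) != self.n_populations:
            raise ValueError(
                f"population_names has {len(self.population_names)} entries "
                f"for n_populations={self.n_populations}"
            )
        if self.latent_loading_endoAtoh1 < 0 or self.latent_loading_Atoh1HA < 0:
            raise ValueError("latent loadings must be non-negative")
        if self.latent_noise_sd <= 0:
            raise ValueError("latent_noise_sd must be > 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        unknown = set(self.continuum_populations) - set(self.population_names)
        if unknown:
            raise ValueError(f"continuum populations not in population set: {unknown}")
        budget = (self.n_populations * self.n_marker_genes_per_population
                  + self.n_gradient_genes + 3)
        if budget > self.n_genes:
            raise ValueError(
                f"marker/gradient gene demand ({budget}) exceeds n_genes "
                f"({self.n_genes})"
            )

    def cells_for(self, population: str) -> int:
        if isinstance(self.cells_per_population, Mapping):
            return int(self.cells_per_population.get(population, 0))
        return int(self.cells_per_population)


@dataclass
class UmiDataset:
    """A gene x cell UMI count matrix with per-cell metadata.

    ``counts`` is a dense non-negative integer matrix (genes in rows).
    ``cell_meta`` is indexed by cell id with columns ``sample``,
    ``condition``, ``true_population`` and ``true_latent`` (NaN outside the
    conversion continuum).  ``special_features`` maps the roles
    ``Atoh1_endogenous`` / ``Atoh1_HA`` / ``tdTomato`` to gene symbols.
    ``truth`` carries generative quantities (expected counts, population
    mean fractions) when the dataset is synthetic, else ``None``.
    """

    counts: np.ndarray
    gene_names: pd.Index
    cell_ids: pd.Index
    cell_meta: pd.DataFrame
    special_features: dict[str, str] = field(default_factory=dict)
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_names = pd.Index(self.gene_names, name="gene")
        self.cell_ids = pd.Index(self.cell_ids, name="cell_id")
        if self.counts.shape != (len(self.gene_names), len(self.cell_ids)):
            raise ValueError("counts shape does not match gene/cell names")
        if len(self.cell_meta) != len(self.cell_ids):
            raise ValueError("cell_meta rows != number of cells")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        for role, symbol in self.special_features.items():
            if (self.gene_names == symbol).sum() != 1:
                raise ValueError(f"special feature {role}={symbol!r} must occur exactly once")

    # -- basic accessors ----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def cell_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def log2p1(self) -> np.ndarray:
        """log2(count + 1), the working expression scale of the pipeline."""
        return np.log2(self.counts + 1.0)

    def gene_index(self, symbol: str) -> int:
        idx = np.flatnonzero(self.gene_names == symbol)
        if idx.size != 1:
            raise KeyError(symbol)
        return int(idx[0])

    def subset_genes(self, keep: np.ndarray) -> "UmiDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        genes = self.gene_names[keep]
        special = {r: s for r, s in self.special_features.items() if s in set(genes)}
        return UmiDataset(self.counts[keep], genes, self.cell_ids,
                          self.cell_meta, special, self.truth)

    def subset_cells(self, keep: np.ndarray) -> "UmiDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return UmiDataset(self.counts[:, keep], self.gene_names,
                          self.cell_ids[keep],
                          self.cell_meta.iloc[keep], dict(self.special_features),
                          self.truth)


@dataclass(frozen=True)
class BulkSimTruth:
    """Generative truth of the bulk RNA-seq simulator.

    ``group_log2_means`` (genes x cell types) are log2 expected counts at
    unit library factor; biological duplicates share the group mean.
    ``de_genes`` lists genes with a programmed fold change (columns
    ``gene``, ``contrast``, ``log2fc``).  ``nb_dispersion = 0`` is the
    zero-noise limit: counts are the rounded means.
    """

    group_log2_means: pd.DataFrame
    gene_lengths: pd.Series
    tf_genes: tuple[str, ...]
    de_genes: pd.DataFrame
    n_replicates: int = 2
    nb_dispersion: float = 20.0
    replicate_noise_sd: float = 0.3
    library_factor_sd: float = 0.15

    def __post_init__(self) -> None:
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    @property
    def cell_types(self) -> list[str]:
        return list(self.group_log2_means.columns)

    def sample_sheet(self) -> pd.DataFrame:
        rows = [
            {"sample": f"{ct}_rep{r + 1}", "cell_type": ct, "replicate": r + 1}
            for ct in self.cell_types
            for r in range(self.n_replicates)
        ]
        return pd.DataFrame(rows).set_index("sample")


@dataclass(frozen=True)
class QpcrSimTruth:
    """Generative truth of the single-cell qPCR simulator.

    ``log2_expr`` (cells x assays) is true expression on a scale where 0
    sits at the limit of detection; ``efficiency`` is per-assay PCR
    efficiency in (0.7, 1.1]; ``intercept_ct`` is the Ct of the top
    (undiluted) point of the dilution series.  The single-cell model is
    ``Cq = LOD-Ct - log2(expr) / log2(1 + efficiency) + noise`` so that Cq
    increases as concentration decreases; cells below the detection floor
    (log2 expr < 0) and a ``dropout_rate`` fraction of chambers do not
    amplify (missing Cq).  ``melt_multipeak_prob`` chambers show a second
    melt peak (primer-dimer artifact).
    """

    log2_expr: pd.DataFrame
    cell_types: pd.Series
    efficiency: pd.Series
    intercept_ct: pd.Series
    cq_noise_sd: float = 0.1
    dropout_rate: float = 0.02
    melt_multipeak_prob: float = 0.05
    n_dilutions: int = 15
    dilution_factor: float = 3.0

    def __post_init__(self) -> None:
        if (self.efficiency <= 0).any() or (self.efficiency > 1.1).any():
            raise ValueError("efficiency must lie in (0, 1.1]")

    @property
    def assays(self) -> list[str]:
        return list(self.log2_expr.columns)

    def lod_ct(self) -> pd.Series:
        """Noiseless Ct of the most dilute standard (the true LOD-Ct)."""
        lam = np.log2(1.0 + self.efficiency)
        steps = (self.n_dilutions - 1) * np.log2(self.dilution_factor)
        return self.intercept_ct + steps / lam


# ---------------------------------------------------------------------------
# RNG streams: one child stream per artifact, derived from the master seed
# ---------------------------------------------------------------------------

_ARTIFACT_STREAM = {"umi": 0, "bulk": 1, "qpcr": 2, "counts": 3}


def artifact_rng(seed: int, artifact: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _ARTIFACT_STREAM[artifact]])


def _nb_sample(rng: np.random.Generator, mu: np.ndarray,
               theta: np.ndarray) -> np.ndarray:
    """NB(mu, theta) with variance mu + mu^2/theta via gamma-Poisson."""
    mu = np.asarray(mu, dtype=float)
    theta = np.broadcast_to(np.asarray(theta, dtype=float), mu.shape)
    lam = rng.gamma(shape=theta, scale=np.where(theta > 0, mu / np.maximum(theta, 1e-300), 0.0))
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# Single-cell UMI generator
# ---------------------------------------------------------------------------

def _latent_interval(population: str, order: Sequence[str]) -> tuple[float, float]:
    k = list(order).index(population)
    n = len(order)
    return k / n, (k + 1) / n


def _gene_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign symbols, baseline log2 expression and structural roles."""
    n = config.n_genes
    names = [f"Gene{i + 1:04d}" for i in range(n)]
    base = rng.normal(1.0, 1.0, size=n)
    table = pd.DataFrame({"gene": names, "base_log2": base})
    table["marker_of"] = ""
    table["gradient"] = 0.0  # signed log2 loading on the conversion coordinate

    cursor = 0
    for pop in config.population_names:
        block = range(cursor, cursor + config.n_marker_genes_per_population)
        named = _NAMED_MARKERS.get(pop, ())
        for j, gi in enumerate(block):
            if j < len(named):
                table.loc[gi, "gene"] = named[j]
            table.loc[gi, "marker_of"] = pop
        cursor += config.n_marker_genes_per_population

    n_grad = config.n_gradient_genes
    rising = range(cursor, cursor + n_grad // 2)
    falling = range(cursor + n_grad // 2, cursor + n_grad)
    for j, gi in enumerate(rising):
        if j < len(_RISING_TFS):
            table.loc[gi, "gene"] = _RISING_TFS[j]
        table.loc[gi, "gradient"] = config.gradient_log2_loading
    for j, gi in enumerate(falling):
        if j < len(_FALLING_TFS):
            table.loc[gi, "gene"] = _FALLING_TFS[j]
        table.loc[gi, "gradient"] = -config.gradient_log2_loading
    # gradient genes start from a common moderate baseline so both rising and
    # falling arms stay in a detectable range
    table.loc[table["gradient"] != 0, "base_log2"] = rng.normal(
        3.0, 0.5, size=(table["gradient"] != 0).sum())
    return table


def gen_umi_dataset(config: SimConfig) -> UmiDataset:
    """Simulate the gene x cell UMI matrix for the configured populations.

    Marker genes get a ``marker_log2_boost`` increase of relative log2
    expression in their own population.  Cells of continuum populations
    draw a latent ``s`` uniformly from that population's sub-interval of
    [0, 1] (SC1 lowest, cHC3 highest); conversion-program (gradient) genes
    and the two Atoh1 features move with ``s``.  Mature hair cells
    (populations named OHC/IHC) express the rising conversion program at
    full level but carry no transgene.  Counts are negative binomial with
    per-cell log-normal library size.
    """
    rng = artifact_rng(config.seed, "umi")
    genes = _gene_table(config, rng)

    populations = [p for p in config.population_names if config.cells_for(p) > 0]
    cells = []
    for pop in populations:
        npop = config.cells_for(pop)
        cond = _POPULATION_CONDITION.get(pop, "Coch_P12")
        reps = list(config.batch_labels) or ["rep1"]
        for i in range(npop):
            rep = reps[i % len(reps)]
            cells.append({"true_population": pop, "condition": cond,
                          "sample": f"{cond}_{rep}"})
    meta = pd.DataFrame(cells)
    n_cells = len(meta)
    if n_cells == 0:
        raise ValueError("configuration yields zero cells")
    meta.index = pd.Index([f"cell{i + 1:04d}" for i in range(n_cells)], name="cell_id")

    continuum = list(config.continuum_populations)
    s = np.full(n_cells, np.nan)
    for pop in continuum:
        mask = (meta["true_population"] == pop).to_numpy()
        lo, hi = _latent_interval(pop, continuum)
        s[mask] = rng.uniform(lo, hi, size=mask.sum())
    meta["true_latent"] = s

    # program level: continuum cells follow s; mature HCs express the rising
    # program fully; other populations do not engage it
    prog = np.where(np.isnan(s), 0.0, s)
    is_hc = meta["true_population"].isin(["OHC", "IHC"]).to_numpy()
    prog[is_hc] = 1.0

    # relative log2 expression eta (genes x cells)
    eta = np.tile(genes["base_log2"].to_numpy()[:, None], (1, n_cells))
    pop_arr = meta["true_population"].to_numpy()
    for pop in populations:
        mask = pop_arr == pop
        markers = (genes["marker_of"] == pop).to_numpy()
        eta[np.ix_(markers, mask)] += config.marker_log2_boost
    grad = genes["gradient"].to_numpy()
    eta += np.outer(np.clip(grad, 0, None), prog)       # rising program
    in_cont = ~np.isnan(s)
    eta[:, in_cont] += np.outer(np.clip(grad, None, 0), s[in_cont])  # falling

    # special features appended after the generic/marker genes
    gene_names = list(genes["gene"])
    theta = np.full(config.n_genes + 3, config.nb_dispersion)
    # conversion-program genes respond to a shared regulatory state and are
    # modeled as less bursty than background genes
    theta[: config.n_genes][genes["gradient"].to_numpy() != 0] = config.program_dispersion
    theta[-3:] = config.transgene_dispersion
    special_rows = np.zeros((3, n_cells))
    sc_lineage = meta["true_population"].isin(_SC_LINEAGE).to_numpy()
    noise_endo = rng.normal(0.0, config.latent_noise_sd, size=n_cells)
    noise_ha = rng.normal(0.0, config.latent_noise_sd, size=n_cells)
    s_safe = np.where(in_cont, s, 0.0)
    atoh1_offset = 5.0  # log2 baseline of the Atoh1 features at s = 0
    special_rows[0] = np.where(
        in_cont, atoh1_offset + config.latent_loading_endoAtoh1 * s_safe + noise_endo, -np.inf)
    special_rows[1] = np.where(
        in_cont, atoh1_offset + config.latent_loading_Atoh1HA * s_safe + noise_ha, -np.inf)
    special_rows[2] = np.where(sc_lineage, 7.0, -np.inf)  # tdTomato reporter
    eta = np.vstack([eta, special_rows])
    gene_names += [ATOH1_ENDOGENOUS, ATOH1_HA, TDTOMATO]

    rel = np.exp2(eta)
    frac = rel / rel.sum(axis=0, keepdims=True)
    mu_log, sigma_log = config.library_size_lognormal
    lib = rng.lognormal(mu_log, sigma_log, size=n_cells)
    mu = frac * lib[None, :]
    counts = _nb_sample(rng, mu, theta[:, None])

    # generative per-population mean fractions, for marker-program checks
    pop_frac = pd.DataFrame(
        {pop: frac[:, pop_arr == pop].mean(axis=1) for pop in populations},
        index=pd.Index(gene_names, name="gene"))

    # library size is a per-cell property; recorded so cell QC can always
    # refer to the original sequencing depth regardless of gene subsetting
    meta["lib_size"] = counts.sum(axis=0)

    truth = {"config": config, "expected_counts": mu,
             "population_mean_fraction": pop_frac, "dispersion": theta}
    special = {"Atoh1_endogenous": ATOH1_ENDOGENOUS, "Atoh1_HA": ATOH1_HA,
               "tdTomato": TDTOMATO}
    return UmiDataset(counts, pd.Index(gene_names, name="gene"),
                      meta.index, meta, special, truth)


def default_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """The default well-separated 7-population x 100-cell preset."""
    return replace(SimConfig(seed=seed), **overrides) if overrides else SimConfig(seed=seed)


def continuum_sim_config(seed: int = 0, cells_per_population: int = 150,
                         **overrides) -> SimConfig:
    """600-cell preset restricted to the SC1->cHC1->cHC2->cHC3 continuum."""
    cfg = SimConfig(
        n_populations=4,
        population_names=CONTINUUM_POPULATIONS,
        continuum_populations=CONTINUUM_POPULATIONS,
        cells_per_population=cells_per_population,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Bulk RNA-seq generator
# ---------------------------------------------------------------------------

BULK_CELL_TYPES = ("SC_P26", "cHC_P33", "OHC_P7", "OHC_P22", "IHC_P74")


def default_bulk_truth(n_genes: int = 2000, n_tf: int = 300,
                       block_size: int = 120, seed: int = 0) -> BulkSimTruth:
    """Construct the default five-cell-type bulk truth.

    Expression programs are block-structured so that the converted-HC
    profile sits between supporting cells and immature OHCs but closest to
    OHC P7: an SC program, a pan-HC program partially engaged by cHCs, an
    immature-HC program shared by cHC and OHC P7, a maturation program
    (OHC P22, weakly IHC) and an IHC program.  The first ``n_tf`` genes are
    the transcription-factor panel; each program block starts inside it so
    TF-restricted analyses see the same structure.
    """
    rng = np.random.default_rng([int(seed), 17])
    tf_names = [f"Tf{i + 1:04d}" for i in range(n_tf)]
    for j, sym in enumerate(("Atoh1", "Pou4f3", "Isl1", "Barhl1", "Lhx3",
                             "Gata3", "Hes6", "Neurod6", "Ikzf2", "Sall1",
                             "Aff3", "Zbtb20", "Rorb", "Id1", "Hes1")):
        tf_names[j] = sym
    names = tf_names + [f"Gene{i + 1:04d}" for i in range(n_genes - n_tf)]

    base = rng.normal(6.0, 1.5, size=n_genes)
    means = pd.DataFrame({ct: base.copy() for ct in BULK_CELL_TYPES},
                         index=pd.Index(names, name="gene"))

    # each block: first 30 genes drawn from the TF panel, rest from the
    # non-TF pool, so TF-only analyses retain every program
    n_tf_per_block = 30
    tf_cursor, other_cursor = 15, n_tf  # skip the named TFs for block bookkeeping
    programs = {
        "sc":  {"SC_P26": 3.2},
        "hc":  {"cHC_P33": 2.6, "OHC_P7": 3.2, "OHC_P22": 3.2, "IHC_P74": 3.2},
        "imm": {"cHC_P33": 2.9, "OHC_P7": 3.2},
        "mat": {"OHC_P22": 3.2, "IHC_P74": 1.3},
        "ihc": {"IHC_P74": 3.2},
    }
    block_members: dict[str, list[str]] = {}
    for prog, effects in programs.items():
        rows = list(range(tf_cursor, tf_cursor + n_tf_per_block))
        rows += list(range(other_cursor, other_cursor + block_size - n_tf_per_block))
        tf_cursor += n_tf_per_block
        other_cursor += block_size - n_tf_per_block
        block_members[prog] = [names[i] for i in rows]
        for ct, eff in effects.items():
            means.iloc[rows, means.columns.get_loc(ct)] += eff
    # named TFs follow the conversion program
    for sym in ("Atoh1", "Pou4f3", "Barhl1", "Lhx3", "Gata3", "Hes6", "Neurod6"):
        means.loc[sym, ["cHC_P33", "OHC_P7"]] += 2.2
    for sym in ("Isl1", "Ikzf2", "Sall1", "Aff3"):
        means.loc[sym, ["OHC_P22", "IHC_P74"]] += 2.5
    for sym in ("Rorb", "Id1", "Hes1", "Zbtb20"):
        means.loc[sym, "SC_P26"] += 2.5

    de_rows = []
    for ct in BULK_CELL_TYPES:
        others = [c for c in BULK_CELL_TYPES if c != ct]
        fc = means[ct].to_numpy()[:, None] - means[others].to_numpy()
        for j, other in enumerate(others):
            hit = np.abs(fc[:, j]) >= 2.0
            for gi in np.flatnonzero(hit):
                if ct < other:
                    de_rows.append({"gene": names[gi], "contrast": f"{ct}_vs_{other}",
                                    "log2fc": float(fc[gi, j])})
    de = pd.DataFrame(de_rows).drop_duplicates()

    lengths = pd.Series(
        np.round(rng.lognormal(np.log(1500.0), 0.6, size=n_genes)).astype(int) + 200,
        index=means.index, name="length_bp")
    return BulkSimTruth(group_log2_means=means, gene_lengths=lengths,
                        tf_genes=tuple(tf_names), de_genes=de)


def gen_bulk_dataset(truth: BulkSimTruth, seed: int = 0) -> pd.DataFrame:
    """Simulate the bulk count table (gene, length_bp, one column/replicate).

    Each replicate draws NB counts around ``2**group_log2_means`` with a
    per-gene-per-replicate log2 amplification noise (whole-transcriptome
    amplification variability) and a per-sample library-depth factor.
    With ``nb_dispersion = 0`` all noise is switched off and counts are
    the rounded group means (the zero-dispersion limit).
    """
    if truth.gene_lengths.isna().any():
        raise ValueError("gene lengths contain missing values")
    rng = artifact_rng(seed, "bulk")
    sheet = truth.sample_sheet()
    out = pd.DataFrame({"gene": truth.group_log2_means.index,
                        "length_bp": truth.gene_lengths.to_numpy()})
    n_genes = len(out)
    for sample, row in sheet.iterrows():
        mu_log2 = truth.group_log2_means[row["cell_type"]].to_numpy()
        if truth.nb_dispersion == 0:
            counts = np.round(np.exp2(mu_log2)).astype(int)
        else:
            noise = rng.normal(0.0, truth.replicate_noise_sd, size=n_genes)
            libf = rng.lognormal(0.0, truth.library_factor_sd)
            mu = np.exp2(mu_log2 + noise) * libf
            counts = _nb_sample(rng, mu, truth.nb_dispersion)
        out[sample] = counts
    return out


# ---------------------------------------------------------------------------
# Single-cell qPCR generator
# ---------------------------------------------------------------------------

QPCR_CELL_COUNTS = {"SC": 27, "cHC": 25, "OHC": 16}
_QPCR_TO_BULK = {"SC": "SC_P26", "cHC": "cHC_P33", "OHC": "OHC_P22"}


def default_qpcr_truth(bulk_truth: BulkSimTruth | None = None,
                       n_assays: int = 89, seed: int = 0,
                       platform_noise_sd: float = 0.3,
                       cell_noise_sd: float = 1.0) -> QpcrSimTruth:
    """Build a qPCR truth whose assay panel shares expression truth with the
    bulk simulator (enabling cross-platform concordance analyses).

    The panel prefers genes differentially expressed among SC/cHC/OHC in
    the bulk truth (the validated TF list), topped up with stable
    high-expression genes standing in for housekeeping controls.
    ``platform_noise_sd`` perturbs each gene x cell-type mean independently
    per platform; ``cell_noise_sd`` is biological cell-to-cell spread.
    """
    if bulk_truth is None:
        bulk_truth = default_bulk_truth(seed=seed)
    rng = artifact_rng(seed, "qpcr")
    means = bulk_truth.group_log2_means[list(_QPCR_TO_BULK.values())]
    spread = means.max(axis=1) - means.min(axis=1)
    # panel balanced over the three pairwise contrasts, as a DE-validated
    # assay panel would be, topped up with stable (housekeeping-like) genes
    cols = list(means.columns)
    per_pair = (n_assays - 2) // 3
    panel: list[str] = []
    for i in range(3):
        a, b = cols[i], cols[(i + 1) % 3]
        ranked = (means[a] - means[b]).abs().sort_values(ascending=False).index
        panel += [g for g in ranked if g not in panel][:per_pair]
    for g in spread.sort_values(ascending=False).index:
        if len(panel) >= n_assays - 2:
            break
        if g not in panel:
            panel.append(g)
    for g in spread.sort_values().index:
        if len(panel) >= n_assays:
            break
        if g not in panel:
            panel.append(g)  # housekeeping-like stable genes

    cells, types = [], []
    for ct, n in QPCR_CELL_COUNTS.items():
        for i in range(n):
            cells.append(f"{ct}_{i + 1:02d}")
            types.append(ct)
    cell_types = pd.Series(types, index=pd.Index(cells, name="cell_id"),
                           name="cell_type")

    # rescale bulk log2 means into the qPCR dynamic range ([0, ~9] above LOD)
    sub = means.loc[panel]
    center = float(sub.to_numpy().mean())
    log2e = np.empty((len(cells), len(panel)))
    for ci, ct in enumerate(types):
        m = sub[_QPCR_TO_BULK[ct]].to_numpy() - center + 4.5
        m = m + rng.normal(0.0, platform_noise_sd, size=len(panel))
        log2e[ci] = m + rng.normal(0.0, cell_noise_sd, size=len(panel))
    expr = pd.DataFrame(log2e, index=cell_types.index,
                        columns=pd.Index(panel, name="assay"))

    eff = pd.Series(rng.uniform(0.85, 1.05, size=len(panel)), index=expr.columns,
                    name="efficiency")
    intercept = pd.Series(rng.uniform(8.0, 12.0, size=len(panel)),
                          index=expr.columns, name="intercept_ct")
    return QpcrSimTruth(log2_expr=expr, cell_types=cell_types,
                        efficiency=eff, intercept_ct=intercept)


def gen_qpcr_plate(truth: QpcrSimTruth, seed: int = 0
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a single-cell qPCR plate and its dilution-series table.

    Returns ``(plate, dilution)``.  ``plate`` is long-format with columns
    assay, chamber, cell_id, cell_type, Cq (NaN = no amplification) and
    melt_peaks.  ``dilution`` has one row per assay x dilution step with
    the relative concentration and observed Ct; Ct spacing between
    consecutive threefold dilutions is ``log2(3)/log2(1+efficiency)``.
    """
    rng = artifact_rng(seed, "qpcr")
    lam = np.log2(1.0 + truth.efficiency)

    dil_rows = []
    for assay in truth.assays:
        for d in range(truth.n_dilutions):
            ct = (truth.intercept_ct[assay]
                  + d * np.log2(truth.dilution_factor) / lam[assay])
            if truth.cq_noise_sd > 0:
                ct += rng.normal(0.0, truth.cq_noise_sd)
            dil_rows.append({"assay": assay, "dilution_step": d,
                             "relative_conc": truth.dilution_factor ** (-d),
                             "Ct": ct})
    dilution = pd.DataFrame(dil_rows)

    lod = truth.lod_ct()
    rows = []
    chamber = 0
    for cell_id, ct_type in truth.cell_types.items():
        for assay in truth.assays:
            chamber += 1
            x = truth.log2_expr.loc[cell_id, assay]
            detected = np.isfinite(x) and x >= 0 and rng.uniform() >= truth.dropout_rate
            if detected:
                cq = lod[assay] - x / lam[assay]
                if truth.cq_noise_sd > 0:
                    cq += rng.normal(0.0, truth.cq_noise_sd)
                cq = float(max(cq, 1.0))
            else:
                cq = np.nan
            peaks = 1 + int(rng.uniform() < truth.melt_multipeak_prob)
            rows.append({"assay": assay, "chamber": chamber, "cell_id": cell_id,
                         "cell_type": ct_type, "Cq": cq, "melt_peaks": peaks})
    plate = pd.DataFrame(rows)
    return plate, dilution


# ---------------------------------------------------------------------------
# Imaging cell-count generator (conversion-rate inputs)
# ---------------------------------------------------------------------------

def gen_count_table(rates: Mapping[str, float], n_cells: int = 150,
                    n_samples: int = 8, seed: int = 0,
                    dislodged_rate: float = 0.0) -> pd.DataFrame:
    """Simulate per-sample reporter / double-positive cell counts.

    For each condition, ``n_samples`` samples each contribute ``n_cells``
    reporter-positive cells; the double-positive count is binomial with the
    condition's conversion rate.  ``dislodged_rate`` adds counted-then-
    excluded endogenous cells (cluster rule of the imaging quantification).
    """
    rng = artifact_rng(seed, "counts")
    rows = []
    for cond, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {cond!r} outside [0, 1]")
        for i in range(n_samples):
            double = int(rng.binomial(n_cells, rate))
            excl = int(rng.binomial(n_cells, dislodged_rate)) if dislodged_rate else 0
            rows.append({"sample": f"{cond}_s{i + 1}", "condition": cond,
                         "reporter_pos": n_cells + excl,
                         "double_pos": double + excl,
                         "excluded": excl})
    return pd.DataFrame(rows)
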