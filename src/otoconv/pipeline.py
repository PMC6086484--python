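"""End-to-end orchestration, configuration and shared file I/O.

Artifacts on disk are plain text: UMI matrices as Matrix Market
coordinate triplets with gene/barcode/cell-metadata TSV sidecars, bulk
counts and qPCR plates as TSV, and a JSON manifest per run recording the
configuration, master seed and SHA-256 of every output so a run is
reproducible from the manifest alone.  Stages execute in dependency
order (simulate -> preprocess -> cluster -> trajectory / network ->
bulk-de -> qpcr -> validate -> convert-stats); later stages re-read
earlier outputs from the run directory, so any suffix of the pipeline
can be re-run alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from . import bulk as bulk_mod
from . import cluster as cluster_mod
from . import network as network_mod
from . import preprocess as pre_mod
from . import qpcr as qpcr_mod
from . import synthetic as syn
from . import trajectory as traj_mod
from . import validate as val_mod

__all__ = [
    "PipelineConfig",
    "run_all",
    "write_umi_bundle",
    "read_umi_bundle",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "ALL_STAGES",
]

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "preprocess", "cluster", "trajectory", "network",
              "bulk-de", "qpcr", "validate", "convert-stats")


# ---------------------------------------------------------------------------
# Matrix bundle I/O
# ---------------------------------------------------------------------------

def write_umi_bundle(dataset: syn.UmiDataset, outdir: str | Path) -> Path:
    """Write matrix.mtx + genes.tsv + barcodes.tsv + cell_meta.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx",
                     sp.coo_matrix(dataset.counts.astype(np.int64)))
    pd.Series(dataset.gene_names).to_csv(outdir / "genes.tsv", sep="\t",
                                         index=False, header=False)
    pd.Series(dataset.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t",
                                       index=False, header=False)
    dataset.cell_meta.to_csv(outdir / "cell_meta.tsv", sep="\t")
    return outdir


def read_umi_bundle(indir: str | Path) -> syn.UmiDataset:
    indir = Path(indir)
    for name in ("matrix.mtx", "genes.tsv", "barcodes.tsv", "cell_meta.tsv"):
        if not (indir / name).exists():
            raise FileNotFoundError(f"missing bundle file: {indir / name}")
    mat = scipy.io.mmread(indir / "matrix.mtx")
    dense = np.asarray(mat.todense() if sp.issparse(mat) else mat)
    if not np.allclose(dense, np.round(dense)):
        raise ValueError("count matrix contains non-integer values")
    counts = np.round(dense).astype(np.int64)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    meta = pd.read_csv(indir / "cell_meta.tsv", sep="\t", index_col=0)
    special = {}
    for role, symbol in (("Atoh1_endogenous", syn.ATOH1_ENDOGENOUS),
                         ("Atoh1_HA", syn.ATOH1_HA),
                         ("tdTomato", syn.TDTOMATO)):
        if (genes == symbol).sum() == 1:
            special[role] = symbol
    return syn.UmiDataset(counts, pd.Index(genes), pd.Index(barcodes),
                          meta, special)


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_csv(path, sep="\t")
    return path


def read_matrix_tsv(path: str | Path, integer: bool = False) -> pd.DataFrame:
    out = pd.read_csv(path, sep="\t", index_col=0)
    if integer:
        vals = out.to_numpy()
        if not np.allclose(vals, np.round(vals)):
            raise ValueError(f"non-integer values in count file {path}")
        out = out.round().astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Run directory, master seed and per-stage parameter blocks."""

    outdir: Path = Path("otoconv_run")
    seed: int = 0
    log_level: str = "INFO"
    stages: tuple[str, ...] = ALL_STAGES
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        raw["outdir"] = Path(raw.get("outdir", "otoconv_run"))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def stage_params(self, stage: str) -> dict:
        return dict(self.params.get(stage, {}))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

class _Runner:
    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.ctx: dict = {}
        self.outputs: list[Path] = []

    # -- helpers ------------------------------------------------------------
    def _emit(self, rel: str, obj) -> Path:
        path = self.outdir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        if isinstance(obj, pd.DataFrame) or isinstance(obj, pd.Series):
            obj.to_csv(path, sep="\t")
        else:
            path.write_text(json.dumps(obj, indent=2, default=str) + "\n")
        self.outputs.append(path)
        return path

    def _need(self, key: str, loader, path: Path):
        if key not in self.ctx:
            if not path.exists():
                raise FileNotFoundError(
                    f"stage input missing: {path} (run the producing stage first)")
            self.ctx[key] = loader(path)
        return self.ctx[key]

    # -- stages -------------------------------------------------------------
    def simulate(self) -> None:
        p = self.config.stage_params("simulate")
        seed = int(p.get("seed", self.config.seed))
        preset = p.get("preset", "default")
        if preset == "continuum":
            cfg = syn.continuum_sim_config(seed=seed)
        else:
            cfg = syn.default_sim_config(seed=seed)
        umi = syn.gen_umi_dataset(cfg)
        write_umi_bundle(umi, self.outdir / "umi")
        self.outputs += sorted((self.outdir / "umi").glob("*"))
        self.ctx["umi"] = umi

        truth = syn.default_bulk_truth(seed=seed)
        table = syn.gen_bulk_dataset(truth, seed=seed)
        self._emit("bulk/counts.tsv", table.set_index("gene"))
        self._emit("bulk/sample_sheet.tsv", truth.sample_sheet())
        self.ctx["bulk_table"] = table
        self.ctx["bulk_truth"] = truth

        qt = syn.default_qpcr_truth(truth, seed=seed)
        plate, dilution = syn.gen_qpcr_plate(qt, seed=seed)
        self._emit("qpcr/plate.tsv", plate.set_index("chamber"))
        self._emit("qpcr/dilution_series.tsv", dilution.set_index("assay"))
        self.ctx["qpcr_plate"] = plate
        self.ctx["qpcr_dilution"] = dilution
        self.ctx["qpcr_truth"] = qt

        rates = p.get("conversion_rates",
                      {"Atoh1": 0.255, "Atoh1+Isl1": 0.439})
        counts = syn.gen_count_table(rates, seed=seed)
        self._emit("counts/conversion_counts.tsv", counts.set_index("sample"))
        self.ctx["count_table"] = counts

        tf_path = self.outdir / "tf_list.txt"
        tf_path.write_text("\n".join(syn.DEFAULT_TF_GENES) + "\n")
        self.outputs.append(tf_path)

    def preprocess(self) -> None:
        p = self.config.stage_params("preprocess")
        umi = self._need("umi", read_umi_bundle, self.outdir / "umi")
        params = pre_mod.PreprocessParams(
            lib_size_low_quantile=float(p.get("low_quantile", 0.02)),
            lib_size_high_quantile=float(p.get("high_quantile", 0.98)),
            hvg_n_bins=int(p.get("hvg_n_bins", 20)),
            hvg_dispersion_z_min=float(p.get("hvg_z_min", 1.0)),
            seed=int(p.get("seed", self.config.seed)))
        filtered = pre_mod.filter_cells_by_library_size(umi, params)
        down = pre_mod.downsample_to_reference_depth(filtered,
                                                     seed=params.seed)
        data = down.dataset
        blacklists = p.get("blacklists", [])
        if blacklists:
            data = pre_mod.remove_blacklisted_genes(data, blacklists)
        hvg, table = pre_mod.select_hvg(data, params)
        write_umi_bundle(data, self.outdir / "preprocessed")
        self.outputs += sorted((self.outdir / "preprocessed").glob("*"))
        self._emit("preprocessed/hvg.tsv", table)
        self.ctx["preprocessed"] = data
        self.ctx["hvg"] = hvg

    def _load_preprocessed(self):
        data = self._need("preprocessed", read_umi_bundle,
                          self.outdir / "preprocessed")
        if "hvg" not in self.ctx:
            path = self.outdir / "preprocessed" / "hvg.tsv"
            if not path.exists():
                raise FileNotFoundError(f"stage input missing: {path}")
            table = pd.read_csv(path, sep="\t", index_col=0)
            self.ctx["hvg"] = pd.Index(table.index[table["selected"]])
        return data, self.ctx["hvg"]

    def cluster(self) -> None:
        p = self.config.stage_params("cluster")
        data, hvg = self._load_preprocessed()
        result = cluster_mod.run_clustering(
            data, n_pcs=int(p.get("n_pcs", 30)), k=int(p.get("k", 20)),
            perplexity=float(p.get("perplexity", 30.0)),
            seed=int(p.get("seed", self.config.seed)),
            genes=hvg, compute_tsne=bool(p.get("tsne", False)))
        self._emit("cluster/labels.tsv", result.labels)
        if result.markers is not None:
            self._emit("cluster/markers.tsv", result.markers.set_index("gene"))
        self._emit("cluster/composition.tsv", result.composition)
        self._emit("cluster/summary.json",
                   {"n_clusters": result.n_clusters,
                    "modularity": result.modularity})
        if result.embedding_2d is not None:
            self._emit("cluster/embedding.tsv", result.embedding_2d)
        self.ctx["clusters"] = result

    def trajectory(self) -> None:
        p = self.config.stage_params("trajectory")
        data, _ = self._load_preprocessed()
        continuum = p.get("continuum_populations",
                          list(syn.CONTINUUM_POPULATIONS))
        labels = data.cell_meta["true_population"]
        keep = labels.isin(continuum).to_numpy()
        if keep.sum() < 10:
            raise ValueError("too few continuum cells for trajectory fitting")
        sub = data.subset_cells(keep)
        sub_labels = sub.cell_meta["true_population"]
        ordering = traj_mod.select_ordering_genes(sub)
        traj = traj_mod.fit_principal_tree(
            sub, ordering, n_centroids=int(p.get("n_centroids", 25)),
            seed=int(p.get("seed", self.config.seed)))
        tau = traj_mod.assign_pseudotime(traj, p.get("root_cluster", "SC1"),
                                         sub_labels)
        test = traj_mod.test_pseudotime_dependence(sub, tau, genes=ordering)
        profiles = traj_mod.bin_pseudotime_profiles(
            sub, tau, genes=ordering, n_bins=int(p.get("n_bins", 100)))
        self._emit("trajectory/pseudotime.tsv", tau)
        self._emit("trajectory/pseudotime_tests.tsv",
                   test.table.set_index("gene"))
        self._emit("trajectory/binned_profiles.tsv", profiles)
        if "Atoh1_HA" in sub.special_features:
            corr = traj_mod.transgene_correlation(sub, sub_labels)
            self._emit("trajectory/transgene_correlation.json", corr)
        self.ctx["trajectory"] = traj
        self.ctx["pseudotime"] = tau

    def network(self) -> None:
        p = self.config.stage_params("network")
        data, _ = self._load_preprocessed()
        tf_path = Path(p.get("tf_list", self.outdir / "tf_list.txt"))
        if not tf_path.exists():
            raise FileNotFoundError(f"stage input missing: {tf_path}")
        continuum = p.get("continuum_populations",
                          list(syn.CONTINUUM_POPULATIONS))
        mask = data.cell_meta["true_population"].isin(continuum).to_numpy()
        net = network_mod.build_tf_network(
            data, tf_path, cell_filter=mask if mask.any() else None,
            r2_threshold=float(p.get("r2_threshold", 0.25)),
            seed=int(p.get("seed", self.config.seed)))
        edges = net.edges.copy()
        if net.communities is not None:
            edges["community_i"] = net.communities.reindex(
                edges["gene_i"]).to_numpy()
        self._emit("network/edges.tsv", edges.set_index("gene_i"))
        if net.communities is not None:
            self._emit("network/communities.tsv", net.communities)
            self._emit("network/hubs.tsv", net.hubs.set_index("gene"))
            self._emit("network/summary.json", {"modularity": net.modularity})
        self.ctx["network"] = net

    def bulk_de(self) -> None:
        p = self.config.stage_params("bulk-de")
        if "bulk_table" in self.ctx:
            table = self.ctx["bulk_table"]
        else:
            path = self.outdir / "bulk" / "counts.tsv"
            if not path.exists():
                raise FileNotFoundError(f"stage input missing: {path}")
            table = pd.read_csv(path, sep="\t").rename(columns={"Unnamed: 0": "gene"})
        sheet_path = self.outdir / "bulk" / "sample_sheet.tsv"
        if not sheet_path.exists():
            raise FileNotFoundError(f"stage input missing: {sheet_path}")
        sheet = pd.read_csv(sheet_path, sep="\t", index_col=0)
        eset = bulk_mod.BulkExpressionSet.from_table(table, sheet)
        de = bulk_mod.differential_expression(eset)
        tf_path = Path(p.get("tf_list", self.outdir / "tf_list.txt"))
        tf_genes = (pre_mod.read_gene_list(tf_path) if tf_path.exists()
                    else [g for g in eset.counts.index if str(g).startswith("Tf")])
        tf_de = bulk_mod.subset_tf_de(de, tf_genes)
        conc = bulk_mod.replicate_concordance(eset)
        dist = bulk_mod.distance_suite(eset, tf_genes)
        self._emit("bulk/tmm_factors.tsv", eset.tmm())
        self._emit("bulk/de.tsv", de.table.set_index("gene"))
        self._emit("bulk/tf_de.tsv", tf_de.set_index("gene") if len(tf_de)
                   else tf_de)
        self._emit("bulk/concordance.tsv", conc)
        self._emit("bulk/distances.tsv", dist)
        self.ctx["bulk_eset"] = eset
        self.ctx["bulk_de"] = de

    def qpcr(self) -> None:
        p = self.config.stage_params("qpcr")
        if "qpcr_plate" in self.ctx:
            plate_df = self.ctx["qpcr_plate"]
            dilution = self.ctx["qpcr_dilution"]
        else:
            ppath = self.outdir / "qpcr" / "plate.tsv"
            dpath = self.outdir / "qpcr" / "dilution_series.tsv"
            for path in (ppath, dpath):
                if not path.exists():
                    raise FileNotFoundError(f"stage input missing: {path}")
            plate_df = pd.read_csv(ppath, sep="\t")
            dilution = pd.read_csv(dpath, sep="\t")
        plate = qpcr_mod.QpcrPlate(plate_df)
        calib = qpcr_mod.calibrate_lod(dilution)
        clean = qpcr_mod.melt_qc(plate)
        expr = qpcr_mod.cq_to_expression(clean, calib,
                                         lod_mode=p.get("lod_mode", "per_assay"))
        types = (clean.data.drop_duplicates("cell_id")
                 .set_index("cell_id")["cell_type"])
        stats_table = qpcr_mod.group_compare(expr, types)
        self._emit("qpcr/calibration.tsv", calib.table)
        self._emit("qpcr/expression.tsv", expr)
        self._emit("qpcr/group_stats.tsv", stats_table)
        self._emit("qpcr/missingness.tsv", qpcr_mod.missingness_report(plate))
        if "bulk_eset" in self.ctx:
            eset = self.ctx["bulk_eset"]
            conc = qpcr_mod.cross_platform_concordance(
                expr, types, eset.fpkm(), eset.cell_types(),
                type_map={"SC": "SC_P26", "cHC": "cHC_P33",
                          "OHC": "OHC_P22"})
            self._emit("qpcr/cross_platform.tsv", conc)
        self.ctx["qpcr_expression"] = expr

    def validate(self) -> None:
        p = self.config.stage_params("validate")
        data, hvg = self._load_preprocessed()
        if "clusters" in self.ctx:
            labels = self.ctx["clusters"].labels
        else:
            path = self.outdir / "cluster" / "labels.tsv"
            if not path.exists():
                raise FileNotFoundError(f"stage input missing: {path}")
            labels = pd.read_csv(path, sep="\t", index_col=0)["cluster"]
        cfg = val_mod.ClassifierConfig(seed=int(p.get("seed", self.config.seed)))
        matrix = cluster_mod.log_expression_matrix(data, hvg)
        report = val_mod.train_validate_classifier(matrix,
                                                   labels.to_numpy(), cfg)
        self._emit("validate/classifier.json",
                   {"accuracy": report.accuracy,
                    "best_params": report.best_params,
                    "n_train": report.n_train, "n_test": report.n_test})
        self._emit("validate/confusion.tsv", report.confusion)
        self.ctx["classifier"] = report

    def convert_stats(self) -> None:
        if "count_table" in self.ctx:
            table = self.ctx["count_table"]
        else:
            path = self.outdir / "counts" / "conversion_counts.tsv"
            if not path.exists():
                raise FileNotFoundError(f"stage input missing: {path}")
            table = pd.read_csv(path, sep="\t")
        rates = val_mod.conversion_rate(table)
        result = val_mod.compare_rates(rates)
        self._emit("counts/rates.tsv", rates.set_index("sample"))
        self._emit("counts/rate_summary.tsv", result["summary"])
        self._emit("counts/rate_tests.tsv", result["tests"])
        self.ctx["rates"] = rates


_STAGE_METHODS = {
    "simulate": _Runner.simulate,
    "preprocess": _Runner.preprocess,
    "cluster": _Runner.cluster,
    "trajectory": _Runner.trajectory,
    "network": _Runner.network,
    "bulk-de": _Runner.bulk_de,
    "qpcr": _Runner.qpcr,
    "validate": _Runner.validate,
    "convert-stats": _Runner.convert_stats,
}


def run_all(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order and write a manifest.

    Raises on the first failing stage, naming it; outputs of completed
    stages are retained.  Returns the runner context (in-memory results
    keyed by artifact name).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    runner = _Runner(config)
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        logger.info("running stage %s", stage)
        try:
            _STAGE_METHODS[stage](runner)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest = {
        "seed": config.seed,
        "stages": list(config.stages),
        "params": config.params,
        "outputs": {str(p.relative_to(runner.outdir)): _sha256(p)
                    for p in sorted(set(runner.outputs))},
    }
    (runner.outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n")
    return runner.ctx
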