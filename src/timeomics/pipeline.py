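"""End-to-end orchestration: quantify -> impute -> univariate -> latent ->
network -> causality -> profiles, from one config, with full provenance.

Every intermediate table is written as TSV into the output directory and a
JSON run log records the seed, all parameters, the feature counts surviving
each filter and any warnings. One global seed governs all stochastic
stages; per-stage seeds are derived from it deterministically, so a fixed
config yields byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .synthetic import (
    DesignSpec,
    SimParams,
    TruthConfig,
    simulate_dataset,
    write_dataset,
)
from .causality import GrangerParams, granger_all_pairs, prepare_series
from .datatypes import FeatureMatrix, SpectralCountTable
from .errors import PipelineError
from .impute import ImputationParams, impute_sknn
from .latent import autoscale, pca, plsda, spls
from .network import (
    merge_networks,
    pairwise_correlation,
    spls_similarity,
    threshold_network,
    write_edge_list,
    write_graphml,
)
from .profiles import bicluster_heatmap, bin_aggregate, percent_of_max
from .quantify import (
    FilterParams,
    compute_nsaf,
    filter_metabolite_presence,
    filter_min_abundance,
    filter_replicate_presence,
    merge_blocks,
    normalize_metabolites,
    normalize_physio_t0,
    presence_report,
)
from .univariate import anova_tukey, kruskal_wallis, log_transform

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Everything one run needs; every field has a recorded default."""

    # inputs: file paths, or a synthetic block
    synthetic: bool = True
    counts_path: str | None = None
    metabolites_path: str | None = None
    physio_path: str | None = None
    design_path: str | None = None
    binmap_path: str | None = None
    seed: int = 0
    outdir: str = "timeomics_out"
    # synthetic generation
    design: DesignSpec = field(default_factory=DesignSpec)
    sim: SimParams = field(default_factory=SimParams)
    truth: TruthConfig = field(default_factory=TruthConfig)
    # quantify
    tau: float = 0.001
    abundance_mode: str = "max"
    n_required: int | None = None
    alt_times: int = 5
    alt_mode: str = "distinct_times"
    metabolite_min_samples: int = 18
    t0_exempt: tuple[str, ...] = ("FvFm",)
    # impute
    impute_k: int = 10
    # univariate
    alpha: float = 0.05
    # latent
    ncomp: int = 3
    keepX: int = 50
    log_proteins: bool = True
    log_metabolites: bool = True
    # network
    spls_cutoff: float = 0.9
    corr_cutoff: float = 0.9
    corr_method: str = "pearson"
    # causality
    lag: int = 1
    granger_alpha: float = 0.05
    granger_max_features: int = 30
    # profiles
    cluster_metric: str = "euclidean"
    cluster_method: str = "complete"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["t0_exempt"] = list(self.t0_exempt)
        d["design"]["timepoints"] = list(self.design.timepoints)
        d["sim"]["length_range"] = list(self.sim.length_range)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "design" in data and isinstance(data["design"], dict):
            d = dict(data["design"])
            if "timepoints" in d:
                d["timepoints"] = tuple(d["timepoints"])
            data["design"] = DesignSpec(**d)
        if "sim" in data and isinstance(data["sim"], dict):
            s = dict(data["sim"])
            if "length_range" in s:
                s["length_range"] = tuple(s["length_range"])
            data["sim"] = SimParams(**s)
        if "truth" in data and isinstance(data["truth"], dict):
            data["truth"] = TruthConfig(**data["truth"])
        if "t0_exempt" in data:
            data["t0_exempt"] = tuple(data["t0_exempt"])
        return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from TOML or YAML."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    if path.suffix == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    elif path.suffix in (".yaml", ".yml"):
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        raise PipelineError(f"unsupported config format: {path.suffix}")
    return RunConfig.from_dict(data)


@dataclass
class RunReport:
    """What a run produced: survivor counts per stage, warnings, outputs."""

    outdir: str
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    outputs: list = field(default_factory=list)


class _Stage:
    """Context manager that names the failing stage and leaves a marker."""

    def __init__(self, name: str, outdir: Path):
        self.name, self.outdir = name, outdir

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            (self.outdir / "FAILED").write_text(f"stage: {self.name}\nerror: {exc}\n")
            raise PipelineError(f"stage '{self.name}' failed: {exc}") from exc
        return False


def _write(report: RunReport, frame: pd.DataFrame, path: Path, label: str = "feature") -> None:
    tio.write_feature_table(frame, path, label)
    report.outputs.append(path.name)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in fixed order, writing every intermediate table."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(outdir=str(outdir))
    captured: list[str] = []

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        _run_stages(config, outdir, report)
        captured = sorted({str(w.message) for w in caught})
    report.warnings = captured

    log = {
        "seed": config.seed,
        "config": config.to_dict(),
        "counts": report.counts,
        "warnings": report.warnings,
        "outputs": sorted(report.outputs),
        "status": "ok",
    }
    tio.write_json(log, outdir / "run_log.json")
    return report


def _run_stages(config: RunConfig, outdir: Path, report: RunReport) -> None:
    fp = FilterParams(
        tau=config.tau,
        n_required=config.n_required,
        alt_times=config.alt_times,
        metabolite_min_samples=config.metabolite_min_samples,
        abundance_mode=config.abundance_mode,
        alt_mode=config.alt_mode,
    )

    with _Stage("inputs", outdir):
        binmap = None
        if config.synthetic:
            spec = DesignSpec(
                timepoints=config.design.timepoints,
                n_replicates=config.design.n_replicates,
                seed=config.seed,
            )
            dataset = simulate_dataset(spec, config.sim, config.truth)
            write_dataset(dataset, outdir / "inputs", seed=config.seed)
            design = dataset.design
            proteome = dataset.proteome
            metabolites = dataset.metabolites
            physio = dataset.physio
        else:
            for name in ("counts_path", "metabolites_path", "physio_path", "design_path"):
                value = getattr(config, name)
                if value is None or not Path(value).exists():
                    raise FileNotFoundError(f"{name} missing or not found: {value}")
            design = tio.read_design(config.design_path)
            proteome = SpectralCountTable.from_frame(tio.read_feature_table(config.counts_path))
            metabolites = tio.read_feature_table(config.metabolites_path)
            physio = tio.read_feature_table(config.physio_path)
        if config.binmap_path is not None:
            binmap = tio.read_bin_map(config.binmap_path)
        report.counts["proteins_raw"] = len(proteome.counts)
        report.counts["metabolites_raw"] = len(metabolites)
        report.counts["physio_variables"] = len(physio)

    with _Stage("quantify", outdir):
        nsaf = compute_nsaf(proteome)
        nsaf = filter_min_abundance(nsaf, tau=config.tau, mode=config.abundance_mode)
        report.counts["proteins_min_abundance"] = len(nsaf)
        _write(report, presence_report(nsaf, design, fp), outdir / "protein_filter_report.tsv")
        nsaf = filter_replicate_presence(nsaf, design, fp)
        report.counts["proteins_presence"] = len(nsaf)
        _write(report, nsaf, outdir / "nsaf.tsv", "protein")

        met = normalize_metabolites(metabolites)
        _write(
            report,
            presence_report(met, design, fp, metabolite=True),
            outdir / "metabolite_filter_report.tsv",
        )
        met = filter_metabolite_presence(met, design, fp)
        report.counts["metabolites_presence"] = len(met)

    with _Stage("impute", outdir):
        if met.isna().any().any():
            n_complete = int((~met.isna().any(axis=1)).sum())
            k = min(config.impute_k, max(n_complete, 1))
            if k < config.impute_k:
                warnings.warn(f"imputation K clamped from {config.impute_k} to {k}")
            result = impute_sknn(met, ImputationParams(k=k))
            met = result.data
            result.audit.to_csv(outdir / "imputation_audit.tsv", sep="\t", index=False)
            report.outputs.append("imputation_audit.tsv")
            report.counts["imputed_cells"] = len(result.audit)
        else:
            report.counts["imputed_cells"] = 0
        _write(report, met, outdir / "metabolites_normalized.tsv", "metabolite")

        phys = normalize_physio_t0(physio, design, exempt=config.t0_exempt) if len(physio) else physio
        _write(report, phys, outdir / "physiology_normalized.tsv", "variable")

    with _Stage("univariate", outdir):
        groups = design["time_h"]
        nsaf_log = log_transform(nsaf)
        kw = kruskal_wallis(nsaf_log, groups)
        _write(report, kw, outdir / "stats_proteins_kruskal.tsv")
        stats_frames = {"protein": kw}
        for label, block in (("metabolite", met), ("physiology", phys)):
            if len(block) >= 1:
                res = anova_tukey(block, groups, alpha=config.alpha)
                _write(report, res, outdir / f"stats_{label}_anova.tsv")
                stats_frames[label] = res
        report.counts["proteins_significant"] = int((kw["p_adjusted"] <= config.alpha).sum())

    with _Stage("latent", outdir):
        prot_for_latent = nsaf_log if config.log_proteins else nsaf
        met_for_latent = log_transform(met) if config.log_metabolites else met
        merged = merge_blocks(prot_for_latent, met_for_latent, phys, design)
        _write(report, merged.values, outdir / "merged_matrix.tsv")
        report.counts["features_merged"] = len(merged.values)

        scaled, scaling = autoscale(merged.values.T)
        ncomp = min(config.ncomp, scaled.shape[0] - 1, scaled.shape[1])
        pca_model = pca(scaled, ncomp)
        _write(report, pca_model.x_scores, outdir / "pca_scores.tsv", "sample")
        _write(report, pca_model.x_weights, outdir / "pca_loadings.tsv")

        labels = design.loc[scaled.index, "time_h"]
        plsda_model = plsda(scaled, labels, ncomp=min(ncomp, 2))
        _write(report, plsda_model.x_scores, outdir / "plsda_scores.tsv", "sample")

        predictor_cols = [
            c for c in scaled.columns if merged.blocks.get(c) in ("protein", "metabolite")
        ]
        response_cols = [c for c in scaled.columns if merged.blocks.get(c) == "physiology"]
        spls_model = None
        if predictor_cols and response_cols:
            X = scaled[predictor_cols]
            Y = scaled[response_cols]
            keep = min(config.keepX, X.shape[1])
            spls_model = spls(X, Y, ncomp=ncomp, keepX=keep)
            _write(report, spls_model.x_scores, outdir / "spls_scores.tsv", "sample")
            _write(report, spls_model.x_weights, outdir / "spls_x_weights.tsv")
            _write(report, spls_model.y_weights, outdir / "spls_y_weights.tsv")
            tio.write_json(spls_model.summary(), outdir / "spls_summary.json")

    with _Stage("network", outdir):
        node_blocks = merged.blocks.to_dict()
        nets = []
        if spls_model is not None:
            sim = spls_similarity(spls_model, X, Y)
            nets.append(
                threshold_network(
                    sim, config.spls_cutoff, node_blocks, provenance="spls-similarity"
                )
            )
        corr = pairwise_correlation(scaled[predictor_cols].T, method=config.corr_method)
        nets.append(
            threshold_network(
                corr, config.corr_cutoff, node_blocks, provenance="pairwise-correlation"
            )
        )
        net = merge_networks(*nets)
        write_graphml(net, outdir / "network.graphml")
        write_edge_list(net, outdir / "network_edges.tsv")
        report.outputs.extend(["network.graphml", "network_edges.tsv"])
        report.counts["network_edges"] = net.number_of_edges()
        report.counts["network_nodes"] = net.number_of_nodes()

    with _Stage("causality", outdir):
        p_by_feature = {}
        prefix = {"protein": "prot", "metabolite": "met", "physiology": "phys"}
        for label, frame in stats_frames.items():
            for feat, p in frame["p_raw"].items():
                p_by_feature[f"{prefix[label]}:{feat}"] = p
        ranked = sorted(
            (f for f in merged.values.index if f in p_by_feature),
            key=lambda f: (p_by_feature[f], f),
        )[: config.granger_max_features]
        series, degenerate = prepare_series(merged.values.loc[ranked], design)
        granger = granger_all_pairs(
            series, GrangerParams(lag=config.lag, alpha=config.granger_alpha)
        )
        granger.to_csv(outdir / "granger_results.tsv", sep="\t", index=False)
        report.outputs.append("granger_results.tsv")
        report.counts["granger_tested"] = int((~granger["degenerate"]).sum())
        report.counts["granger_significant"] = int(granger["significant"].sum())

    with _Stage("profiles", outdir):
        prof = percent_of_max(nsaf, design)
        _write(report, prof, outdir / "protein_profiles_pctmax.tsv", "protein")
        significant = kw.index[(kw["p_adjusted"] <= config.alpha) & ~kw["degenerate"]]
        if binmap is not None:
            bins = bin_aggregate(prof, binmap, significant=significant)
            _write(report, bins.mean, outdir / "bin_profiles_mean.tsv", "bin")
            _write(report, bins.sd, outdir / "bin_profiles_sd.tsv", "bin")
            report.counts["bins_profiled"] = len(bins.mean)
            report.counts["features_unmapped"] = len(bins.unmapped)
        cluster_input = prof.loc[[f for f in prof.index if f in set(significant)]]
        if cluster_input.shape[0] >= 2 and cluster_input.shape[1] >= 2:
            bic = bicluster_heatmap(
                cluster_input, metric=config.cluster_metric, method=config.cluster_method
            )
            _write(report, bic.matrix, outdir / "heatmap_matrix.tsv")
            (outdir / "heatmap_rows.nwk").write_text(bic.row_newick + "\n")
            (outdir / "heatmap_cols.nwk").write_text(bic.col_newick + "\n")
            report.outputs.extend(["heatmap_rows.nwk", "heatmap_cols.nwk"])
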