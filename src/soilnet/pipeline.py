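"""End-to-end orchestration of the four analysis stages.

``run_pipeline`` takes one :class:`PipelineConfig` (input files or a
synthetic-generation request), executes ordination, variance
partitioning, response ratios and the four co-occurrence networks
(CF/COF × enzyme–ion/ion–ion), and returns a :class:`ReportBundle`;
``write_report`` serialises the bundle into stable, deterministic files.

One global seed is fanned out to the stages by fixed offsets (generator:
seed; NMDS ions/enzymes: seed+11/+12; VPA permutations ions/enzymes:
seed+21/+22; Louvain: seed+31), so a stage re-run in isolation with its
offset seed reproduces the pipeline's result.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .effect_size import DEFAULT_LAMBDA, records_to_frame, rr_table
from .io_model import (
    Metadata,
    SampleTable,
    ValidationError,
    concat_tables,
    read_metadata,
    read_sample_table,
    summarize_design,
)
from .network import (
    build_network,
    detect_communities,
    export_network,
    network_stats,
    pearson_matrix,
)
from .ordination import bray_curtis, nmds
from .synthetic import SynthConfig, generate_dataset, truth_report
from .varpart import blocks_from_metadata, hellinger, vpa_with_significance

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"

SEED_OFFSETS = {
    "nmds_ions": 11,
    "nmds_enzymes": 12,
    "vpa_ions": 21,
    "vpa_enzymes": 22,
    "louvain": 31,
}


class ConfigError(ValidationError):
    """The pipeline configuration is incomplete or contradictory."""


@dataclass
class PipelineConfig:
    ion_table: str | None = None
    enzyme_table: str | None = None
    metadata: str | None = None
    generate: bool = False
    synth: SynthConfig | None = None
    seed: int = 0
    outdir: str = "results"
    k: int = 2
    n_restarts: int = 8
    max_iter: int = 500
    tol: float = 1e-7
    n_permutations: int = 999
    ci_lambda: float = DEFAULT_LAMBDA
    r_cutoff: float = 0.58
    p_cutoff: float = 0.05
    log_level: str = "INFO"

    def __post_init__(self):
        paths_given = all(
            p is not None for p in (self.ion_table, self.enzyme_table, self.metadata)
        )
        if not self.generate and not paths_given:
            raise ConfigError(
                "either set generate=true or give ion_table, enzyme_table "
                "and metadata paths"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("pipeline config file must hold a key-value mapping")
        if "synth" in raw and raw["synth"] is not None:
            from .synthetic import CorrelationBlock

            synth = dict(raw["synth"])
            if "correlation_blocks" in synth:
                synth["correlation_blocks"] = tuple(
                    CorrelationBlock(name, loadings)
                    for name, loadings in synth["correlation_blocks"].items()
                )
            raw["synth"] = SynthConfig(**synth)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class ReportBundle:
    design_summary: object
    ordination: dict          # category → OrdinationResult
    vpa: dict                 # category → VpaResult
    rr_records: list
    networks: dict            # (group, mode) → (CorrelationNetwork, NetworkStats)
    run_metadata: dict
    tables: dict = field(default_factory=dict)
    truth: object = None


def _load_inputs(config: PipelineConfig):
    if config.generate:
        synth = config.synth or SynthConfig(seed=config.seed)
        if config.synth is None:
            logger.info("generating synthetic dataset with default design, seed %d",
                        synth.seed)
        ion_table, enzyme_table, metadata, truth = generate_dataset(synth)
        return ion_table, enzyme_table, metadata, truth
    ion_table = read_sample_table(config.ion_table, category="ion")
    enzyme_table = read_sample_table(config.enzyme_table, category="enzyme")
    metadata = read_metadata(config.metadata)
    metadata.validate_against(ion_table)
    metadata.validate_against(enzyme_table)
    return ion_table, enzyme_table, metadata, None


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages; identical config + seed gives identical bundles."""
    ion_table, enzyme_table, metadata, truth = _load_inputs(config)
    seed = int(config.seed)
    design = summarize_design(metadata)
    logger.info("design: %d sites × %d treatments, %d samples",
                design.n_sites, design.n_treatments, design.n_samples_total)

    ordination = {}
    vpa = {}
    for category, table in (("ions", ion_table), ("enzymes", enzyme_table)):
        dist = bray_curtis(table)
        ordination[category] = nmds(
            dist, k=config.k, n_restarts=config.n_restarts,
            max_iter=config.max_iter, tol=config.tol,
            seed=seed + SEED_OFFSETS[f"nmds_{category}"],
        )
        logger.info("NMDS %s: stress %.4f (R² nonlinear %.4f, linear %.4f)",
                    category, ordination[category].stress,
                    ordination[category].r2_nonlinear,
                    ordination[category].r2_linear)
        blocks = blocks_from_metadata(metadata, table.sample_ids)
        response = hellinger(table)
        vpa[category] = vpa_with_significance(
            response, *blocks, adjusted=True,
            n_permutations=config.n_permutations,
            seed=seed + SEED_OFFSETS[f"vpa_{category}"],
        )
        logger.info("VPA %s: total explained %.2f%%, residual %.2f%%",
                    category, 100 * vpa[category].total_explained,
                    100 * vpa[category].residual)

    rr_records = rr_table(ion_table, enzyme_table, metadata, lam=config.ci_lambda)

    combined = concat_tables(ion_table, enzyme_table)
    networks = {}
    for group in ("CF", "COF"):
        group_samples = metadata.samples_where(fertilization=group)
        for mode, table in (("enzyme-ion", combined), ("ion-ion", ion_table)):
            corr = pearson_matrix(table, group_samples)
            net = build_network(corr, r_cutoff=config.r_cutoff,
                                p_cutoff=config.p_cutoff, mode=mode)
            if net.n_edges > 0:
                detect_communities(net, seed=seed + SEED_OFFSETS["louvain"])
            stats = network_stats(net)
            networks[(group, mode)] = (net, stats)
            logger.info("network %s/%s: %d nodes, %d edges (%d positive)",
                        group, mode, stats.n_nodes, stats.n_edges,
                        stats.n_positive)

    run_metadata = {
        "seed": seed,
        "soilnet_version": __version__,
        "generated": bool(config.generate),
        "r_cutoff": config.r_cutoff,
        "p_cutoff": config.p_cutoff,
        "n_permutations": config.n_permutations,
        "ci_lambda": config.ci_lambda,
        "n_restarts": config.n_restarts,
    }
    return ReportBundle(
        design_summary=design,
        ordination=ordination,
        vpa=vpa,
        rr_records=rr_records,
        networks=networks,
        run_metadata=run_metadata,
        tables={"ions": ion_table, "enzymes": enzyme_table, "metadata": metadata},
        truth=truth,
    )


def write_report(bundle: ReportBundle, outdir) -> dict:
    """Write the per-stage tables and a machine-readable summary.

    File names are stable: ``summary.json``, ``ordination_<cat>.tsv``,
    ``vpa_<cat>.tsv``, ``response_ratios.tsv``, ``network_stats.tsv`` and
    ``network_<group>_<mode>.gexf``.  Re-running on an identical bundle
    reproduces the files byte for byte.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    summary = {
        "design": vars(bundle.design_summary).copy(),
        "run": bundle.run_metadata,
        "ordination": {
            cat: {
                "stress": res.stress,
                "r2_nonlinear": res.r2_nonlinear,
                "r2_linear": res.r2_linear,
                "converged": res.converged,
            }
            for cat, res in bundle.ordination.items()
        },
        "vpa": {
            cat: {
                "total_explained_pct": 100.0 * res.total_explained,
                "residual_pct": 100.0 * res.residual,
                "fractions_pct": {k: 100.0 * v for k, v in res.as_dict().items()},
                "p_values": res.testable_fraction_pvalues,
            }
            for cat, res in bundle.vpa.items()
        },
        "rr": {
            "n_records": len(bundle.rr_records),
            "n_significant": sum(r.significant for r in bundle.rr_records),
            "n_excluded": sum(r.excluded_reason is not None for r in bundle.rr_records),
        },
        "networks": {
            f"{group}_{mode}": {
                "n_nodes": stats.n_nodes,
                "n_edges": stats.n_edges,
                "n_positive": stats.n_positive,
                "n_negative": stats.n_negative,
                "average_degree_paper": stats.average_degree_paper,
                "modularity": stats.modularity,
                "n_communities": stats.n_communities,
            }
            for (group, mode), (_, stats) in bundle.networks.items()
        },
    }
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True,
                                       allow_nan=True) + "\n")
    written["summary"] = summary_path

    for cat, res in bundle.ordination.items():
        frame = pd.DataFrame(
            res.coordinates,
            index=pd.Index(res.sample_ids, name="sample_id"),
            columns=[f"NMDS{i + 1}" for i in range(res.coordinates.shape[1])],
        )
        frame["per_sample_fit"] = res.per_sample_fit
        path = outdir / f"ordination_{cat}.tsv"
        frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
        written[f"ordination_{cat}"] = path

    for cat, res in bundle.vpa.items():
        path = outdir / f"vpa_{cat}.tsv"
        res.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
        written[f"vpa_{cat}"] = path

    rr_path = outdir / "response_ratios.tsv"
    records_to_frame(bundle.rr_records).to_csv(rr_path, sep="\t", index=False,
                                               float_format=FLOAT_FORMAT)
    written["response_ratios"] = rr_path

    stats_rows = []
    for (group, mode), (net, stats) in bundle.networks.items():
        stats_rows.append({
            "group": group,
            "mode": mode,
            "n_nodes": stats.n_nodes,
            "n_edges": stats.n_edges,
            "n_positive": stats.n_positive,
            "n_negative": stats.n_negative,
            "average_degree_paper": stats.average_degree_paper,
            "average_degree_standard": stats.average_degree_standard,
            "average_path_length": stats.average_path_length,
            "diameter": stats.diameter,
            "modularity": stats.modularity,
            "n_communities": stats.n_communities,
        })
        net_path = outdir / f"network_{group}_{mode}.gexf"
        if net.n_edges > 0:
            export_network(net, net_path, format="gexf")
            written[f"network_{group}_{mode}"] = net_path
    stats_path = outdir / "network_stats.tsv"
    pd.DataFrame(stats_rows).to_csv(stats_path, sep="\t", index=False,
                                    float_format=FLOAT_FORMAT)
    written["network_stats"] = stats_path

    if bundle.truth is not None:
        truth_path = outdir / "truth.csv"
        truth_report(bundle.truth).to_csv(truth_path, index=False,
                                          float_format=FLOAT_FORMAT)
        written["truth"] = truth_path
    return written
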