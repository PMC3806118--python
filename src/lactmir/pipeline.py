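"""End-to-end orchestration: screen -> cluster -> consensus -> enrich -> pathways.

A single flat YAML config names every input file and threshold; the run
writes one deterministic TSV report per stage plus a key/value summary, so
identical inputs and config always produce a byte-identical bundle.  Each
stage logs one structured line with its input size, thresholds and output
size, which makes a real-data rerun auditable against published narrative
counts (e.g. 56 screened -> 25 kept -> 22 with targets -> 215 genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import clustering, de_screen, ontology
from . import pathways as pathways_mod
from .consensus import ConsensusTable, MultiplicityStats, consensus, coverage_report, multiplicity_stats
from .io_tables import (
    read_annotation_table,
    read_count_table,
    read_pathway_map,
    read_prediction_table,
    write_report,
)

__all__ = ["PipelineConfig", "PipelineError", "validate_config", "save_config", "run_pipeline"]

logger = logging.getLogger("lactmir.pipeline")

_REQUIRED_PATHS = ("counts", "obo", "annotations", "pathway_map")
_DEFAULTS = dict(
    min_expression=50.0,
    fc_cut=1.0,
    p_cut=0.01,
    count_basis="raw",
    sided="two",
    stage_pair=["peak", "early"],
    k=5,
    metric="sqeuclidean",
    rescale=False,
    overrides={},
    min_support=3,
    alpha=0.6,
    sig=0.05,
    fdr=False,
    level=2,
    min_genes=3,
    seed=0,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    counts: str
    predictions: dict[str, str]  # program name -> path
    obo: str
    annotations: str
    pathway_map: str
    out_dir: str
    min_expression: float = 50.0
    fc_cut: float = 1.0
    p_cut: float = 0.01
    count_basis: str = "raw"
    sided: str = "two"
    stage_pair: list = field(default_factory=lambda: ["peak", "early"])
    k: int = 5
    metric: str = "sqeuclidean"
    rescale: bool = False
    overrides: dict[str, str] = field(default_factory=dict)
    min_support: int = 3
    alpha: float = 0.6
    sig: float = 0.05
    fdr: bool = False
    level: int = 2
    min_genes: int = 3
    seed: int = 0


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a flat YAML config; unknown keys are rejected and
    all missing input paths are reported together."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    required = [*(k for k in _REQUIRED_PATHS if k not in raw)]
    if "predictions" not in raw:
        required.append("predictions")
    if "out_dir" not in raw:
        required.append("out_dir")
    if required:
        raise ValueError(f"missing required config keys: {sorted(required)}")
    cfg = PipelineConfig(**{**_DEFAULTS, **raw})
    missing = [
        f"{key}={getattr(cfg, key)}"
        for key in _REQUIRED_PATHS
        if not Path(getattr(cfg, key)).exists()
    ]
    missing += [
        f"predictions[{prog}]={p}" for prog, p in cfg.predictions.items() if not Path(p).exists()
    ]
    if missing:
        raise ValueError(f"input files not found: {missing}")
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


@dataclass
class ReportBundle:
    screened: list
    assignment: clustering.ClusterAssignment
    consensus: ConsensusTable
    stats: MultiplicityStats
    coverage: tuple[list[str], list[str]]
    enrichment: dict[str, list]
    level_table: object
    pathway_report: pathways_mod.PathwayReport
    summary: dict


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"{name}: {exc}") from exc
        return inner
    return wrap


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute all stages in order and write the report bundle to
    ``cfg.out_dir``.  Any stage error halts the run with a stage-named
    message; an empty screen stops after stage 1 explicitly."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    screen_cfg = de_screen.ScreenConfig(
        min_expression=cfg.min_expression,
        fc_cut=cfg.fc_cut,
        p_cut=cfg.p_cut,
        count_basis=cfg.count_basis,
        sided=cfg.sided,
    )

    # stage 1: differential-expression screen
    counts = _stage("screen")(read_count_table)(cfg.counts)
    results = _stage("screen")(de_screen.differential_table)(
        counts, tuple(cfg.stage_pair), screen_cfg
    )
    screened = [(m, r) for m, r in sorted(results.items()) if r.significant]
    logger.info(
        "screen: %d miRNAs in, thresholds expr>%g |log2fc|>%g p<%g -> %d kept",
        len(results), cfg.min_expression, cfg.fc_cut, cfg.p_cut, len(screened),
    )
    write_report(
        [{"miRNA": m, **asdict(r)} for m, r in sorted(results.items())],
        out / "differential.tsv",
    )
    if not screened:
        raise PipelineError("screen: no miRNA passed the screening rules; pipeline stopped")

    # stage 2: expression-pattern clustering
    @_stage("cluster")
    def _cluster():
        profile = de_screen.expression_profile(counts).loc[[m for m, _ in screened]]
        dmat = clustering.compute_distances(profile, metric=cfg.metric, rescale=cfg.rescale)
        history = clustering.agglomerate(dmat)
        assignment = clustering.cut_tree(history, cfg.k, profile=profile)
        if cfg.overrides:
            assignment = clustering.apply_overrides(assignment, sorted(cfg.overrides.items()))
        return assignment

    assignment = _cluster()
    sizes = {lab: len(assignment.members(lab)) for lab in assignment.cluster_labels()}
    logger.info("cluster: %d miRNAs -> k=%d clusters %s", len(screened), cfg.k, sizes)
    write_report(
        [{"miRNA": m, "cluster": lab} for m, lab in sorted(assignment.labels.items())],
        out / "clusters.tsv",
    )

    # stage 3: consensus target voting
    @_stage("consensus")
    def _consensus():
        tables = [read_prediction_table(p, program=prog) for prog, p in sorted(cfg.predictions.items())]
        voted = consensus(tables, [m for m, _ in screened], cfg.min_support)
        return voted, multiplicity_stats(voted), coverage_report(
            [m for m, _ in screened], voted
        )

    voted, stats, coverage = _consensus()
    logger.info(
        "consensus: %d programs, min_support=%d -> %d genes for %d/%d miRNAs",
        len(cfg.predictions), cfg.min_support, stats.unique_gene_count,
        len(coverage[0]), len(screened),
    )
    write_report(
        [
            {"miRNA": m, "gene": g, "support": s}
            for m in sorted(voted.targets)
            for g, s in voted.targets[m]
        ],
        out / "consensus.tsv",
    )

    # stage 4: ontology enrichment
    @_stage("enrich")
    def _enrich():
        graph = ontology.parse_obo(cfg.obo)
        direct = read_annotation_table(cfg.annotations)
        labels = {m: assignment.labels[m] for m in coverage[0]}
        per_cluster = ontology.enrich_clusters(
            type(assignment)(labels=labels), voted, graph, direct,
            alpha_sig=cfg.sig, fdr=cfg.fdr,
        )
        propagated = ontology.propagate(graph, direct)
        return per_cluster, ontology.level_slice(graph, propagated, cfg.level)

    per_cluster, level_table = _enrich()
    n_sig = {lab: sum(o.significant for o in outs) for lab, outs in per_cluster.items()}
    logger.info("enrich: sig<%g significant terms per cluster %s", cfg.sig, n_sig)
    write_report(
        [
            {"cluster": lab, **asdict(o)}
            for lab in sorted(per_cluster)
            for o in per_cluster[lab]
            if o.significant
        ],
        out / "enriched_terms.tsv",
    )
    write_report(level_table.set_index("term"), out / f"level{cfg.level}_classification.tsv")

    # stage 5: pathway annotation
    @_stage("pathways")
    def _pathways():
        pmap = read_pathway_map(cfg.pathway_map)
        all_genes = {g for pairs in voted.targets.values() for g, _ in pairs}
        report = pathways_mod.annotate_pathways(all_genes, pmap)
        return pathways_mod.filter_min_genes(report, cfg.min_genes)

    pathway_report = _pathways()
    logger.info(
        "pathways: min_genes=%d -> %d pathways reported", cfg.min_genes, len(pathway_report.rows)
    )
    write_report(
        [
            {"pathway": pid, "name": name, "genes": ",".join(genes), "count": count}
            for pid, name, genes, count in pathway_report.rows
        ],
        out / "pathways.tsv",
    )

    summary = {
        "screened_count": len(screened),
        "cluster_sizes": ";".join(f"{lab}={n}" for lab, n in sorted(sizes.items())),
        "mirnas_with_targets": len(coverage[0]),
        "mirnas_without_targets": len(coverage[1]),
        "unique_target_count": stats.unique_gene_count,
        "genes_in_2_or_more_lists": stats.genes_at_least2,
        "max_multiplicity": stats.max_multiplicity,
        "significant_terms_per_cluster": ";".join(
            f"{lab}={n}" for lab, n in sorted(n_sig.items())
        ),
        "pathways_reported": len(pathway_report.rows),
    }
    write_report(summary, out / "summary.tsv")
    return ReportBundle(
        screened=screened,
        assignment=assignment,
        consensus=voted,
        stats=stats,
        coverage=coverage,
        enrichment=per_cluster,
        level_table=level_table,
        pathway_report=pathway_report,
        summary=summary,
    )
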