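"""Seeded generators for every input the pipeline consumes.

Each generator plants known structure — fold changes, pattern memberships,
consensus target sets, over-annotated ontology terms — and returns the
ground truth next to the dataset, so recovery can be asserted exactly.  All
generators are pure functions of their parameters plus the seed.

The count model is Poisson around a fixed per-stage mean: the emulated
design has one pooled library per lactation stage and no biological
replicates, so there is no between-replicate overdispersion to model.
Baseline abundances are drawn log-uniformly between 50 and 50,000 reads per
million, bracketing the published screening floor of 50 rpm and mean
expression above 2,500 rpm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io_tables import AnnotationSet, PredictionTable, ReadCountTable
from . import ontology as _ontology

__all__ = [
    "SimulationTruth",
    "simulate_count_libraries",
    "simulate_patterns",
    "simulate_predictions",
    "simulate_ontology",
]

STAGES = ("early", "peak", "late")

#: Three-stage mean templates (rpm) for the five published pattern shapes:
#: A rising across stages, B dip at peak, C early-low plateau, D peak
#: maximum, E early-high plateau.
PATTERN_TEMPLATES: dict[str, tuple[float, float, float]] = {
    "A": (100.0, 400.0, 900.0),
    "B": (500.0, 100.0, 600.0),
    "C": (100.0, 600.0, 600.0),
    "D": (100.0, 800.0, 200.0),
    "E": (800.0, 250.0, 250.0),
}


@dataclass
class SimulationTruth:
    """Ground truth planted by a generator."""

    seed: int
    de_mirnas: dict[str, float] = field(default_factory=dict)
    cluster_labels: dict[str, str] = field(default_factory=dict)
    consensus_truth: dict[str, list[str]] = field(default_factory=dict)
    enriched_terms: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def simulate_count_libraries(
    n_mirnas: int = 200,
    n_de: int = 20,
    fold_range: tuple[float, float] = (8.0, 8.0),
    depth: int = 1_000_000,
    seed: int = 0,
    stages: tuple[str, ...] = STAGES,
    de_pair: tuple[str, str] = ("peak", "early"),
    baseline_range: tuple[float, float] = (50.0, 50_000.0),
) -> tuple[ReadCountTable, SimulationTruth]:
    """Poisson count libraries with ``n_de`` planted fold changes.

    Every miRNA gets a log-uniform baseline abundance shared by all stages;
    DE miRNAs have the first stage of ``de_pair`` scaled up by a factor
    drawn uniformly from ``fold_range``.  Library totals equal ``depth``.
    """
    if not 0 <= n_de <= n_mirnas:
        raise ValueError("need 0 <= n_de <= n_mirnas")
    if depth < 10**5:
        raise ValueError("depth must be >= 1e5")
    lo, hi = fold_range
    if lo < 1 or hi < lo:
        raise ValueError("fold_range must satisfy 1 <= lo <= hi")
    for stage in de_pair:
        if stage not in stages:
            raise ValueError(f"de_pair stage {stage!r} not in {stages}")
    rng = np.random.default_rng(seed)
    width = len(str(n_mirnas))
    mirnas = [f"mir-{i:0{width}d}" for i in range(1, n_mirnas + 1)]
    log_lo, log_hi = np.log(baseline_range[0]), np.log(baseline_range[1])
    baseline_rpm = np.exp(rng.uniform(log_lo, log_hi, size=n_mirnas))

    means = {stage: baseline_rpm.copy() for stage in stages}
    de_idx = rng.choice(n_mirnas, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    folds = rng.uniform(lo, hi, size=n_de)
    means[de_pair[0]][de_idx] *= folds

    counts = {
        stage: np.minimum(rng.poisson(means[stage] * depth / 1e6), depth)
        for stage in stages
    }
    frame = pd.DataFrame(counts, index=pd.Index(mirnas, name="miRNA"), dtype="int64")
    table = ReadCountTable(counts=frame, total_clean_reads={s: depth for s in stages})
    truth = SimulationTruth(
        seed=seed,
        de_mirnas={mirnas[i]: float(f) for i, f in zip(de_idx, folds)},
    )
    return table, truth


def simulate_patterns(
    k: int = 5,
    n_per_cluster: int = 5,
    noise_sd: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Three-stage expression profiles drawn from ``k`` pattern templates
    plus Gaussian noise (clipped at zero)."""
    if not 1 <= k <= len(PATTERN_TEMPLATES):
        raise ValueError(f"k must be in [1, {len(PATTERN_TEMPLATES)}]")
    rng = np.random.default_rng(seed)
    labels = list(PATTERN_TEMPLATES)[:k]
    rows, ids, truth_labels = [], [], {}
    for lab in labels:
        template = np.array(PATTERN_TEMPLATES[lab])
        for j in range(1, n_per_cluster + 1):
            mirna = f"mir-{lab}{j:02d}"
            noisy = np.clip(template + rng.normal(0.0, noise_sd, size=3), 0.0, None)
            ids.append(mirna)
            rows.append(noisy)
            truth_labels[mirna] = lab
    profile = pd.DataFrame(rows, index=pd.Index(ids, name="miRNA"), columns=list(STAGES))
    return profile, SimulationTruth(seed=seed, cluster_labels=truth_labels)


def simulate_predictions(
    mirnas: list[str],
    gene_universe: list[str],
    n_programs: int = 8,
    planted_per_mirna: int = 10,
    support_at_least: int = 3,
    noise_rate: float = 0.02,
    seed: int = 0,
) -> tuple[list[PredictionTable], SimulationTruth]:
    """Per-program target tables with planted consensus sets plus noise.

    Planted (miRNA, gene) pairs appear in at least ``support_at_least``
    programs; every noise pair appears in at most ``support_at_least - 1``,
    so a support filter at that threshold recovers the planted sets exactly.
    """
    if n_programs < support_at_least:
        raise ValueError("need n_programs >= support_at_least")
    if planted_per_mirna > len(gene_universe):
        raise ValueError("gene universe smaller than planted_per_mirna")
    rng = np.random.default_rng(seed)
    programs = [f"prog{i}" for i in range(1, n_programs + 1)]
    tables = {p: {} for p in programs}
    planted_truth: dict[str, list[str]] = {}
    universe = np.array(sorted({g.upper() for g in gene_universe}))
    for mirna in mirnas:
        planted = rng.choice(universe, size=planted_per_mirna, replace=False)
        planted_truth[mirna] = sorted(planted.tolist())
        for gene in planted:
            support = int(rng.integers(support_at_least, n_programs + 1))
            for pi in rng.choice(n_programs, size=support, replace=False):
                tables[programs[pi]].setdefault(mirna, set()).add(str(gene))
        if noise_rate > 0 and support_at_least > 1:
            others = np.setdiff1d(universe, planted, assume_unique=False)
            picks = rng.random(len(others)) < noise_rate
            for gene in others[picks]:
                support = int(rng.integers(1, support_at_least))
                for pi in rng.choice(n_programs, size=support, replace=False):
                    tables[programs[pi]].setdefault(mirna, set()).add(str(gene))
    prediction_tables = [PredictionTable(program=p, targets=tables[p]) for p in programs]
    return prediction_tables, SimulationTruth(seed=seed, consensus_truth=planted_truth)


@dataclass
class SimulatedOntology:
    graph: "_ontology.OntologyGraph"
    annotations: AnnotationSet
    truth: SimulationTruth
    obo_path: Path | None = None
    annotation_path: Path | None = None
    truth_path: Path | None = None


def simulate_ontology(
    n_terms: int = 50,
    max_depth: int = 5,
    genes: dict[str, list[str]] | list[str] | None = None,
    enriched_spec: list[tuple[str, str | None, float]] | None = None,
    seed: int = 0,
    background_rate: float = 0.05,
    out_dir: str | Path | None = None,
    namespace: str = "biological_process",
) -> SimulatedOntology:
    """Random is_a DAG with uniform background annotation and planted
    cluster-specific over-annotation.

    ``genes`` maps cluster label -> gene list (a flat list becomes one
    cluster "ALL").  ``enriched_spec`` entries are (cluster, term or None,
    odds multiplier); ``None`` picks a random term at level >= 2 and records
    it in the truth.  With ``out_dir`` set, the OBO file, annotation TSV and
    truth JSON are written there.
    """
    if n_terms < 2:
        raise ValueError("need at least 2 terms")
    if genes is None:
        genes = [f"G{i:03d}" for i in range(1, 41)]
    if isinstance(genes, (list, tuple)):
        genes = {"ALL": list(genes)}
    enriched_spec = enriched_spec or []
    rng = np.random.default_rng(seed)

    term_ids = [f"GO:{9000000 + i:07d}" for i in range(n_terms)]
    root = term_ids[0]
    graph = nx.DiGraph()
    graph.add_node(root)
    level = {root: 1}
    for tid in term_ids[1:]:
        eligible = [t for t in graph.nodes if level[t] < max_depth]
        parent = eligible[int(rng.integers(len(eligible)))]
        graph.add_edge(tid, parent)
        level[tid] = level[parent] + 1
        if rng.random() < 0.3:  # occasional second parent -> true DAG
            extra = eligible[int(rng.integers(len(eligible)))]
            if extra != parent:
                graph.add_edge(tid, extra)
                level[tid] = min(level[tid], level[extra] + 1)
    names = {tid: f"simulated term {i}" for i, tid in enumerate(term_ids)}
    namespaces = {tid: namespace for tid in term_ids}
    ontograph = _ontology._finalize(graph, names, namespaces)

    # background annotation: every (gene, non-root term) pair at a uniform rate
    all_genes = sorted({g.upper() for cluster in genes.values() for g in cluster})
    non_root = term_ids[1:]
    direct: dict[str, set[str]] = {}
    mask = rng.random((len(all_genes), len(non_root))) < background_rate
    for gi, gene in enumerate(all_genes):
        terms = {non_root[ti] for ti in np.flatnonzero(mask[gi])}
        if terms:
            direct[gene] = terms

    enriched_truth: dict[str, list[str]] = {}
    deep_terms = [t for t in non_root if ontograph.levels[t] >= 2]
    for cluster, term, multiplier in enriched_spec:
        if cluster not in genes:
            raise ValueError(f"enriched_spec names unknown cluster {cluster!r}")
        if term is None:
            term = deep_terms[int(rng.integers(len(deep_terms)))]
        elif term not in ontograph.graph:
            raise ValueError(f"enriched_spec names unknown term {term!r}")
        rate = min(1.0, background_rate * multiplier)
        for gene in genes[cluster]:
            if rng.random() < rate:
                direct.setdefault(gene.upper(), set()).add(term)
        enriched_truth.setdefault(cluster, []).append(term)

    annotations = AnnotationSet(direct=direct)
    truth = SimulationTruth(seed=seed, enriched_terms=enriched_truth)
    result = SimulatedOntology(graph=ontograph, annotations=annotations, truth=truth)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.obo_path = out_dir / "ontology.obo"
        result.annotation_path = out_dir / "annotations.tsv"
        result.truth_path = out_dir / "truth.json"
        _ontology.write_obo(ontograph, result.obo_path)
        with open(result.annotation_path, "w", encoding="utf-8") as fh:
            fh.write("gene\tterm\n")
            for gene in sorted(direct):
                for term in sorted(direct[gene]):
                    fh.write(f"{gene}\t{term}\n")
        truth.to_json(result.truth_path)
    return result
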