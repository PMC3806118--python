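"""Gene-ontology DAG handling and per-cluster enrichment analysis.

The ontology is read from a minimal OBO subset (``[Term]`` stanzas with
``id``, ``name``, ``namespace``, ``is_a`` and ``is_obsolete``) into a
networkx DiGraph with child -> parent ``is_a`` edges.  Levels are 1-based
shortest paths from each namespace root (the root is level 1), the
convention under which broad terms like "binding" or "cellular process" sit
at level 2.  Annotations obey the true-path rule: a gene annotated to a term
is implicitly annotated to every ancestor.

Two enrichment readouts are provided:

* a per-term *score* summing, over the term itself and every descendant
  carrying direct annotations, ``seq x alpha^dist`` — ``seq`` the number of
  distinct directly annotated sequences at the descendant and ``dist`` the
  shortest descending edge distance (``alpha`` in (0, 1] discounts deep
  detail; default 0.6);
* a two-sided Fisher's exact test per term comparing annotation fractions
  between a test gene set (one expression cluster's targets) and a
  reference set (the other clusters' targets).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from scipy import stats

from .io_tables import AnnotationSet, FormatError, PublishedTargetTable, ValidationError
from .consensus import ConsensusTable

__all__ = [
    "OntologyGraph",
    "PropagatedAnnotation",
    "EnrichmentScore",
    "FisherOutcome",
    "parse_obo",
    "write_obo",
    "propagate",
    "enrichment_score",
    "level_slice",
    "fisher_enrichment",
    "enrich_clusters",
]


@dataclass
class OntologyGraph:
    """is_a DAG over ontology terms (edges run child -> parent)."""

    graph: nx.DiGraph
    names: dict[str, str]
    namespaces: dict[str, str]
    roots: dict[str, str]  # namespace -> root term
    levels: dict[str, int]

    @property
    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    def children(self, term: str) -> list[str]:
        return sorted(self.graph.predecessors(term))

    def parents(self, term: str) -> list[str]:
        return sorted(self.graph.successors(term))

    def descendants(self, term: str) -> set[str]:
        """All terms below ``term`` (terms whose is_a path reaches it)."""
        return nx.ancestors(self.graph, term)


@dataclass
class PropagatedAnnotation:
    """Per-term direct and true-path-propagated gene sets."""

    direct: dict[str, frozenset]
    propagated: dict[str, frozenset]


@dataclass
class EnrichmentScore:
    term: str
    alpha: float
    contributions: list[tuple[str, int, int]]  # (descendant, seq, dist)
    score: float


@dataclass
class FisherOutcome:
    term: str
    test_annotated: int
    test_not: int
    ref_annotated: int
    ref_not: int
    p_value: float
    direction: str  # "over" | "under"
    significant: bool
    q_value: float | None = None


def parse_obo(path: str | Path) -> OntologyGraph:
    """Parse an OBO file (is_a subset); obsolete terms are skipped."""
    terms: dict[str, dict] = {}
    current: dict | None = None
    in_term = False
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("["):
                in_term = line == "[Term]"
                current = {"is_a": []} if in_term else None
                continue
            if not in_term or not line or ":" not in line:
                continue
            tag, value = line.split(":", 1)
            tag, value = tag.strip(), value.split("!")[0].strip()
            if tag == "id":
                current["id"] = value
                terms[value] = current
            elif tag in ("name", "namespace"):
                current[tag] = value
            elif tag == "is_a":
                current["is_a"].append(value)
            elif tag == "is_obsolete" and value.lower() == "true":
                current["obsolete"] = True
    live = {tid: t for tid, t in terms.items() if not t.get("obsolete")}

    graph = nx.DiGraph()
    names, namespaces = {}, {}
    for tid, t in live.items():
        graph.add_node(tid)
        names[tid] = t.get("name", tid)
        namespaces[tid] = t.get("namespace", "unknown")
    for tid, t in live.items():
        for parent in t["is_a"]:
            if parent not in live:
                if parent in terms:
                    continue  # edge into an obsolete term: drop it
                raise FormatError(f"{tid} is_a unknown term {parent}")
            graph.add_edge(tid, parent)
    return _finalize(graph, names, namespaces)


def _finalize(graph: nx.DiGraph, names, namespaces) -> OntologyGraph:
    if not nx.is_directed_acyclic_graph(graph):
        edge = nx.find_cycle(graph)[0]
        raise FormatError(f"ontology is cyclic (e.g. edge {edge[0]} -> {edge[1]})")
    roots: dict[str, str] = {}
    for tid in graph.nodes:
        if graph.out_degree(tid) == 0:  # no parent
            ns = namespaces[tid]
            if ns in roots:
                raise FormatError(f"namespace {ns!r} has multiple roots ({roots[ns]}, {tid})")
            roots[ns] = tid
    levels: dict[str, int] = {}
    down = graph.reverse(copy=False)  # parent -> child
    for ns, root in roots.items():
        for tid, dist in nx.single_source_shortest_path_length(down, root).items():
            levels[tid] = min(levels.get(tid, dist + 1), dist + 1)
    unreachable = set(graph.nodes) - set(levels)
    if unreachable:
        raise FormatError(f"terms not connected to any namespace root: {sorted(unreachable)[:5]}")
    return OntologyGraph(graph=graph, names=names, namespaces=namespaces, roots=roots, levels=levels)


def write_obo(graph: OntologyGraph, path: str | Path) -> None:
    """Serialize back to the OBO subset (deterministic term order)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for tid in graph.terms:
            fh.write(f"\n[Term]\nid: {tid}\nname: {graph.names[tid]}\n")
            fh.write(f"namespace: {graph.namespaces[tid]}\n")
            for parent in graph.parents(tid):
                fh.write(f"is_a: {parent} ! {graph.names[parent]}\n")


def _term_direct(direct: AnnotationSet) -> dict[str, set[str]]:
    per_term: dict[str, set[str]] = {}
    for gene, ts in direct.direct.items():
        for t in ts:
            per_term.setdefault(t, set()).add(gene)
    return per_term


def propagate(graph: OntologyGraph, direct: AnnotationSet) -> PropagatedAnnotation:
    """True-path propagation: each term inherits its descendants' genes."""
    per_term = _term_direct(direct)
    unknown = sorted(set(per_term) - set(graph.graph.nodes))
    if unknown:
        raise ValidationError(f"annotations reference unknown terms: {unknown}")
    propagated: dict[str, frozenset] = {}
    # child -> parent edges: topological order yields children before parents
    for tid in nx.topological_sort(graph.graph):
        genes = set(per_term.get(tid, ()))
        for child in graph.graph.predecessors(tid):
            genes |= propagated[child]
        propagated[tid] = frozenset(genes)
    direct_sets = {tid: frozenset(per_term.get(tid, ())) for tid in graph.graph.nodes}
    return PropagatedAnnotation(direct=direct_sets, propagated=propagated)


def enrichment_score(
    graph: OntologyGraph,
    direct: AnnotationSet,
    term: str,
    alpha: float = 0.6,
) -> EnrichmentScore:
    """Depth-discounted annotation mass at ``term``.

    The term itself contributes its distinct direct-annotation count at
    dist 0; each descendant with direct annotations contributes once, at its
    shortest descending edge distance.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if term not in graph.graph:
        raise ValueError(f"unknown term {term!r}")
    per_term = _term_direct(direct)
    down = graph.graph.reverse(copy=False)
    dists = nx.single_source_shortest_path_length(down, term)
    contributions = []
    for node, dist in sorted(dists.items(), key=lambda kv: (kv[1], kv[0])):
        seq = len(per_term.get(node, ()))
        if seq:
            contributions.append((node, seq, dist))
    score = float(sum(seq * alpha**dist for _, seq, dist in contributions))
    return EnrichmentScore(term=term, alpha=alpha, contributions=contributions, score=score)


def level_slice(graph: OntologyGraph, propagated: PropagatedAnnotation, level: int):
    """(term, name, namespace, propagated gene count) rows at one DAG level."""
    import pandas as pd

    if level < 1:
        raise ValueError("level must be >= 1")
    rows = [
        {
            "term": tid,
            "name": graph.names[tid],
            "namespace": graph.namespaces[tid],
            "gene_count": len(propagated.propagated.get(tid, ())),
        }
        for tid in graph.terms
        if graph.levels[tid] == level
    ]
    frame = pd.DataFrame(rows, columns=["term", "name", "namespace", "gene_count"])
    if len(frame):
        frame = frame.sort_values(
            ["namespace", "gene_count", "term"], ascending=[True, False, True]
        ).reset_index(drop=True)
    return frame


def fisher_enrichment(
    test_genes: set[str],
    reference_genes: set[str],
    propagated: PropagatedAnnotation,
    alpha_sig: float = 0.05,
    fdr: bool = False,
) -> list[FisherOutcome]:
    """Two-sided Fisher's exact test per term on the 2x2 table
    (test annotated / not  vs  reference annotated / not).

    Terms with no annotated gene in either set are omitted (their table is
    degenerate, p = 1).  With ``fdr=True`` significance is judged on
    Benjamini-Hochberg-adjusted q-values instead of raw p-values.
    """
    test_genes, reference_genes = set(test_genes), set(reference_genes)
    if not test_genes or not reference_genes:
        raise ValueError("test and reference sets must be non-empty")
    overlap = test_genes & reference_genes
    if overlap:
        raise ValueError(f"test and reference sets overlap: {sorted(overlap)[:5]}")
    n_test, n_ref = len(test_genes), len(reference_genes)
    outcomes: list[FisherOutcome] = []
    for term in sorted(propagated.propagated):
        genes = propagated.propagated[term]
        a = len(test_genes & genes)
        c = len(reference_genes & genes)
        if a + c == 0:
            continue
        b, d = n_test - a, n_ref - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        direction = "over" if a / n_test > c / n_ref else "under"
        outcomes.append(
            FisherOutcome(
                term=term,
                test_annotated=a,
                test_not=b,
                ref_annotated=c,
                ref_not=d,
                p_value=float(p),
                direction=direction,
                significant=bool(p < alpha_sig),
            )
        )
    if fdr and outcomes:
        m = len(outcomes)
        order = sorted(range(m), key=lambda i: outcomes[i].p_value)
        qs = [0.0] * m
        running = 1.0
        for rank_from_end, i in enumerate(reversed(order)):
            rank = m - rank_from_end
            running = min(running, outcomes[i].p_value * m / rank)
            qs[i] = running
        for i, out in enumerate(outcomes):
            out.q_value = qs[i]
            out.significant = bool(qs[i] < alpha_sig)
    outcomes.sort(key=lambda o: (o.p_value, o.term))
    return outcomes


def enrich_clusters(
    assignment,
    targets: ConsensusTable | PublishedTargetTable,
    graph: OntologyGraph,
    direct: AnnotationSet,
    alpha_sig: float = 0.05,
    fdr: bool = False,
) -> dict[str, list[FisherOutcome]]:
    """Per-cluster Fisher enrichment: each cluster's target genes are the
    test set and the remaining clusters' targets the reference set.

    Genes shared between a cluster and the rest (a gene can be targeted by
    miRNAs in different clusters) are kept in the test set and removed from
    the reference, since the exact test needs disjoint sets.  Clusters with
    no targets are skipped with a warning.
    """
    gene_lists = targets.gene_lists()
    labels = assignment.labels if hasattr(assignment, "labels") else dict(assignment)
    clusters = sorted(set(labels.values()))
    if len(clusters) < 2:
        raise ValueError("need at least two clusters (no reference set otherwise)")
    cluster_genes: dict[str, set[str]] = {
        lab: {
            g.upper()
            for m, l in labels.items()
            if l == lab
            for g in gene_lists.get(m, ())
        }
        for lab in clusters
    }
    propagated = propagate(graph, direct)
    results: dict[str, list[FisherOutcome]] = {}
    for lab in clusters:
        test = cluster_genes[lab]
        if not test:
            warnings.warn(f"cluster {lab!r} has no target genes; skipped", stacklevel=2)
            continue
        reference = set().union(*(cluster_genes[o] for o in clusters if o != lab)) - test
        if not reference:
            warnings.warn(f"cluster {lab!r} has an empty reference set; skipped", stacklevel=2)
            continue
        results[lab] = fisher_enrichment(test, reference, propagated, alpha_sig, fdr)
    return results
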