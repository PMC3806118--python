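"""Consensus voting over target-prediction programs.

Animal miRNA target prediction is noisy, so a candidate target is only
accepted when at least ``min_support`` of the configured programs predict
the same (miRNA, gene) pair.  A program that simply lacks a miRNA still
counts in the denominator — miRNAs absent from most databases end up with
empty candidate lists, which is exactly how they drop out of the analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .io_tables import PredictionTable, PublishedTargetTable, normalize_symbol

__all__ = [
    "ConsensusTable",
    "MultiplicityStats",
    "consensus",
    "multiplicity_stats",
    "coverage_report",
]


@dataclass
class ConsensusTable:
    """Voted candidate targets: per miRNA, (gene, support) pairs sorted by
    support descending then gene name; miRNAs with no surviving gene keep an
    empty list."""

    targets: dict[str, list[tuple[str, int]]]
    min_support: int
    programs: list[str]

    def gene_lists(self) -> dict[str, list[str]]:
        return {m: [g for g, _ in pairs] for m, pairs in self.targets.items()}

    def mirnas_with_targets(self) -> list[str]:
        return sorted(m for m, pairs in self.targets.items() if pairs)


@dataclass
class MultiplicityStats:
    """How often genes recur across the per-miRNA candidate lists.

    ``genes_by_multiplicity[m]`` counts genes appearing in exactly m lists;
    ``genes_at_least2`` counts genes in two or more lists (the convention
    used when reporting "regulated by 2 miRNAs").
    """

    unique_gene_count: int
    genes_by_multiplicity: dict[int, int]
    genes_at_least2: int
    max_multiplicity: int
    max_multiplicity_genes: list[tuple[str, int]]
    total_entries: int


def consensus(
    predictions: list[PredictionTable],
    mirnas: list[str],
    min_support: int = 3,
) -> ConsensusTable:
    """Retain, per miRNA, every gene predicted by >= min_support programs."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    programs = [p.program for p in predictions]
    if len(set(programs)) != len(programs):
        raise ValueError(f"duplicate program names in {programs}")
    if len(programs) < min_support:
        raise ValueError(
            f"min_support={min_support} exceeds the {len(programs)}-program roster"
        )
    targets: dict[str, list[tuple[str, int]]] = {}
    for mirna in mirnas:
        votes: Counter[str] = Counter()
        for table in predictions:
            for gene in table.targets.get(mirna, ()):
                votes[normalize_symbol(gene)] += 1
        kept = [(g, n) for g, n in votes.items() if n >= min_support]
        kept.sort(key=lambda gn: (-gn[1], gn[0]))
        targets[mirna] = kept
    return ConsensusTable(targets=targets, min_support=min_support, programs=programs)


def multiplicity_stats(table: ConsensusTable | PublishedTargetTable) -> MultiplicityStats:
    """Distinct-gene count and per-gene list multiplicity, case-insensitive."""
    if isinstance(table, PublishedTargetTable):
        lists = table.gene_lists()
    else:
        lists = table.gene_lists()
    if not any(lists.values()):
        raise ValueError("no genes in any candidate list")
    multiplicity: Counter[str] = Counter()
    total_entries = 0
    for genes in lists.values():
        seen = {normalize_symbol(g) for g in genes}
        total_entries += len(seen)
        for g in seen:
            multiplicity[g] += 1
    by_level: dict[int, int] = {}
    for g, m in multiplicity.items():
        by_level[m] = by_level.get(m, 0) + 1
    max_mult = max(multiplicity.values())
    max_genes = sorted((g, m) for g, m in multiplicity.items() if m == max_mult)
    return MultiplicityStats(
        unique_gene_count=len(multiplicity),
        genes_by_multiplicity=dict(sorted(by_level.items())),
        genes_at_least2=sum(c for m, c in by_level.items() if m >= 2),
        max_multiplicity=max_mult,
        max_multiplicity_genes=max_genes,
        total_entries=total_entries,
    )


def coverage_report(
    screened: list[str],
    table: ConsensusTable | PublishedTargetTable,
) -> tuple[list[str], list[str]]:
    """Split screened miRNAs into (with >=1 candidate target, without)."""
    if not screened:
        raise ValueError("screened miRNA list is empty")
    lists = table.gene_lists()
    with_targets = sorted(m for m in screened if lists.get(m))
    without = sorted(m for m in screened if not lists.get(m))
    return with_targets, without
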