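"""Pathway membership counting for candidate target genes.

No enrichment statistic is computed here — with only a couple of hundred
candidate genes the useful readout is simply which pathways collect several
of them.  Membership comes from a static gene -> pathway mapping file, so
results do not drift with an online database version.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_tables import PathwayMap, normalize_symbol

__all__ = ["PathwayReport", "annotate_pathways", "filter_min_genes"]


@dataclass
class PathwayReport:
    """Rows of (pathway id, name, matched genes, count), sorted by count
    descending then id; ``unannotated`` holds input genes hitting no
    pathway."""

    rows: list[tuple[str, str, list[str], int]]
    unannotated: list[str]
    min_genes: int = 1

    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for _, _, genes, _ in self.rows:
            out.update(genes)
        return out


def annotate_pathways(genes: set[str], pathway_map: PathwayMap) -> PathwayReport:
    """Intersect an input gene set with every pathway's member set."""
    if not pathway_map.pathways:
        raise ValueError("pathway map is empty")
    gene_set = {normalize_symbol(g) for g in genes}
    rows = []
    hit: set[str] = set()
    for pid in sorted(pathway_map.pathways):
        name, members = pathway_map.pathways[pid]
        matched = sorted(gene_set & members)
        if matched:
            rows.append((pid, name, matched, len(matched)))
            hit.update(matched)
    rows.sort(key=lambda r: (-r[3], r[0]))
    return PathwayReport(rows=rows, unannotated=sorted(gene_set - hit), min_genes=1)


def filter_min_genes(report: PathwayReport, min_genes: int = 3) -> PathwayReport:
    """Keep pathways matched by at least ``min_genes`` input genes
    (default 3, i.e. "more than two")."""
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    rows = [r for r in report.rows if r[3] >= min_genes]
    return PathwayReport(rows=rows, unannotated=list(report.unannotated), min_genes=min_genes)
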