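"""Readers and writers for the pipeline's tabular formats.

All tables are tab-separated UTF-8 with a single header line; lines starting
with ``#`` are comments, except the ``#totals:`` line of a read-count table,
which carries each library's total clean-read count.  Gene symbols are
upper-cased on input so that predictions from programs with different
orthography ("Col3a1" vs "COL3A1") merge correctly.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ReadCountTable",
    "PredictionTable",
    "AnnotationSet",
    "PathwayMap",
    "PublishedTargetTable",
    "read_count_table",
    "write_count_table",
    "read_prediction_table",
    "write_prediction_table",
    "read_annotation_table",
    "read_pathway_map",
    "load_published_targets",
    "load_screened_mirnas",
    "write_report",
]


class FormatError(ValueError):
    """A file does not follow the expected dialect."""


class ValidationError(ValueError):
    """A parsed table violates a domain invariant."""


def normalize_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol: trimmed and upper-cased."""
    return symbol.strip().upper()


@dataclass
class ReadCountTable:
    """Raw miRNA read counts for a set of small-RNA libraries.

    ``counts`` is a miRNA x library DataFrame of non-negative integers;
    ``total_clean_reads`` maps each library id to its total clean-read
    count, the denominator of reads-per-million normalization.
    """

    counts: pd.DataFrame
    total_clean_reads: dict[str, int]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def mirnas(self) -> list[str]:
        return list(self.counts.index)

    def validate(self) -> None:
        missing = set(self.counts.columns) - set(self.total_clean_reads)
        if missing:
            raise FormatError(f"libraries without total_clean_reads: {sorted(missing)}")
        for lib, total in self.total_clean_reads.items():
            if int(total) <= 0:
                raise ValidationError(f"total_clean_reads must be > 0 for library {lib!r}")
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate miRNA ids: {dupes}")
        if (self.counts.values < 0).any():
            raise ValidationError("negative counts are not allowed")
        for lib in self.counts.columns:
            col = self.counts[lib]
            over = col[col > self.total_clean_reads[lib]]
            if len(over):
                raise ValidationError(
                    f"count exceeds total_clean_reads in library {lib!r} "
                    f"for miRNA {over.index[0]!r} ({int(over.iloc[0])} > "
                    f"{self.total_clean_reads[lib]})"
                )


@dataclass
class PredictionTable:
    """Target predictions of one program: miRNA id -> set of gene symbols."""

    program: str
    targets: dict[str, set[str]]

    def __post_init__(self) -> None:
        for mirna, genes in self.targets.items():
            for g in genes:
                if not g:
                    raise ValidationError(f"empty gene symbol for miRNA {mirna!r}")


@dataclass
class AnnotationSet:
    """Direct gene -> ontology-term annotations, prior to DAG propagation."""

    direct: dict[str, set[str]]

    def genes(self) -> set[str]:
        return set(self.direct)

    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.direct.values():
            out |= ts
        return out


@dataclass
class PathwayMap:
    """Static gene -> pathway membership map (e.g. KEGG pathway exports)."""

    pathways: dict[str, tuple[str, set[str]]]  # id -> (name, genes)

    def __post_init__(self) -> None:
        # dict keys are unique by construction; genes normalized by the reader
        for pid, (name, genes) in self.pathways.items():
            if not pid:
                raise ValidationError("empty pathway id")


@dataclass
class PublishedTargetTable:
    """The published consensus target lists: 22 miRNAs with their candidate
    target genes, printed gene count (tg) and supporting-program count (ns)."""

    rows: list[tuple[str, list[str], int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for mirna, genes, tg, ns in self.rows:
            if len(genes) != tg:
                raise ValidationError(
                    f"{mirna}: printed gene count {tg} != list length {len(genes)}"
                )

    @property
    def mirnas(self) -> list[str]:
        return [r[0] for r in self.rows]

    def gene_lists(self) -> dict[str, list[str]]:
        return {mirna: list(genes) for mirna, genes, _, _ in self.rows}


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            yield lineno, line


def read_count_table(path: str | Path) -> ReadCountTable:
    """Parse a read-count table.

    Expected dialect::

        #totals:	early=1000000	peak=1200000
        miRNA	early	peak
        bta-miR-1	5	8

    The ``#totals:`` line must precede the header and name every library.
    """
    totals: dict[str, int] = {}
    header: list[str] | None = None
    rows: list[list] = []
    for lineno, line in _data_lines(path):
        if line.startswith("#totals:"):
            for tok in line[len("#totals:"):].split("\t"):
                tok = tok.strip()
                if not tok:
                    continue
                if "=" not in tok:
                    raise FormatError(f"line {lineno}: malformed totals token {tok!r}")
                lib, val = tok.split("=", 1)
                try:
                    totals[lib.strip()] = int(val)
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: non-integer total {val!r}") from exc
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        if len(fields) != len(header):
            raise FormatError(f"line {lineno}: expected {len(header)} fields, got {len(fields)}")
        mirna = fields[0].strip()
        counts = []
        for lib, tok in zip(header[1:], fields[1:]):
            try:
                value = int(tok)
            except ValueError as exc:
                raise FormatError(
                    f"line {lineno}: non-integer count {tok!r} for miRNA {mirna!r}"
                ) from exc
            counts.append(value)
        rows.append([mirna, *counts])
    if header is None:
        raise FormatError(f"{path}: no header line")
    if not totals:
        raise FormatError(f"{path}: missing '#totals:' line")
    libraries = header[1:]
    missing = [lib for lib in libraries if lib not in totals]
    if missing:
        raise FormatError(f"{path}: no total_clean_reads for libraries {missing}")
    frame = pd.DataFrame(
        [r[1:] for r in rows],
        index=pd.Index([r[0] for r in rows], name="miRNA"),
        columns=libraries,
        dtype="int64",
    )
    return ReadCountTable(counts=frame, total_clean_reads={lib: totals[lib] for lib in libraries})


def write_count_table(table: ReadCountTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        totals = "\t".join(f"{lib}={table.total_clean_reads[lib]}" for lib in table.libraries)
        fh.write(f"#totals:\t{totals}\n")
        fh.write("miRNA\t" + "\t".join(table.libraries) + "\n")
        for mirna in sorted(table.mirnas):
            row = "\t".join(str(int(table.counts.at[mirna, lib])) for lib in table.libraries)
            fh.write(f"{mirna}\t{row}\n")


def read_prediction_table(path: str | Path, program: str) -> PredictionTable:
    """Parse a 2-column (miRNA, gene) prediction file for one program.

    Duplicate rows collapse; symbols are trimmed and upper-cased.
    """
    targets: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0].strip().lower() == "mirna" and lineno == 1:
            continue  # tolerate a header line
        if len(fields) < 2:
            raise FormatError(f"line {lineno}: expected 2 tab-separated fields")
        mirna = fields[0].strip()
        gene = normalize_symbol(fields[1])
        if not mirna:
            raise FormatError(f"line {lineno}: empty miRNA field")
        if not gene:
            raise FormatError(f"line {lineno}: empty gene field")
        targets.setdefault(mirna, set()).add(gene)
    return PredictionTable(program=program, targets=targets)


def write_prediction_table(table: PredictionTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("miRNA\tgene\n")
        for mirna in sorted(table.targets):
            for gene in sorted(table.targets[mirna]):
                fh.write(f"{mirna}\t{gene}\n")


def read_annotation_table(path: str | Path) -> AnnotationSet:
    """Parse a 2-column (gene, term id) annotation TSV."""
    direct: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0].strip().lower() == "gene" and lineno == 1:
            continue
        if len(fields) < 2:
            raise FormatError(f"line {lineno}: expected 2 tab-separated fields")
        gene = normalize_symbol(fields[0])
        term = fields[1].strip()
        if not gene or not term:
            raise FormatError(f"line {lineno}: empty gene or term field")
        direct.setdefault(gene, set()).add(term)
    return AnnotationSet(direct=direct)


def read_pathway_map(path: str | Path) -> PathwayMap:
    """Parse a 3-column (pathway id, pathway name, gene) TSV."""
    pathways: dict[str, tuple[str, set[str]]] = {}
    for lineno, line in _data_lines(path):
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0].strip().lower() in {"pathway", "pathway_id"} and lineno == 1:
            continue
        if len(fields) < 3:
            raise FormatError(f"line {lineno}: expected 3 tab-separated fields")
        pid, name, gene = fields[0].strip(), fields[1].strip(), normalize_symbol(fields[2])
        if not pid or not gene:
            raise FormatError(f"line {lineno}: empty pathway id or gene")
        if pid in pathways and pathways[pid][0] != name:
            raise ValidationError(f"pathway {pid!r} has conflicting names")
        name0, genes = pathways.setdefault(pid, (name, set()))
        genes.add(gene)
    return PathwayMap(pathways=pathways)


def _packaged(name: str):
    return importlib.resources.files("lactmir.data").joinpath(name)


def load_published_targets() -> PublishedTargetTable:
    """The packaged table of published consensus targets (22 miRNAs).

    Gene symbols are stored verbatim as printed (compare case-insensitively;
    :func:`lactmir.consensus.multiplicity_stats` already does).
    """
    rows: list[tuple[str, list[str], int, int]] = []
    with _packaged("published_candidate_targets.tsv").open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("miRNA\t"):
                continue
            mirna, genes, tg, ns = line.split("\t")
            rows.append((mirna, genes.split(","), int(tg), int(ns)))
    return PublishedTargetTable(rows=rows)


def load_screened_mirnas() -> dict[str, str]:
    """The 25 differentially expressed miRNAs and their published expression
    pattern cluster labels (A-E)."""
    labels: dict[str, str] = {}
    with _packaged("screened_mirna_clusters.tsv").open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("miRNA\t"):
                continue
            mirna, cluster = line.split("\t")
            labels[mirna] = cluster
    return labels


def write_report(result, path: str | Path) -> None:
    """Write any pipeline product to a deterministic TSV report.

    Accepts a DataFrame (written sorted by index), a mapping (two-column
    key/value report) or a sequence of dataclass-like records exposing
    ``_fields``/``__dict__``.  Same input always produces byte-identical
    output.
    """
    path = Path(path)
    if isinstance(result, ReadCountTable):
        write_count_table(result, path)
        return
    if isinstance(result, PredictionTable):
        write_prediction_table(result, path)
        return
    if isinstance(result, pd.DataFrame):
        frame = result.sort_index()
        frame.to_csv(path, sep="\t", lineterminator="\n")
        return
    if isinstance(result, Mapping):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("key\tvalue\n")
            for key in sorted(result, key=str):
                fh.write(f"{key}\t{result[key]}\n")
        return
    if isinstance(result, Sequence):
        records = []
        for item in result:
            if hasattr(item, "__dataclass_fields__"):
                records.append({k: getattr(item, k) for k in item.__dataclass_fields__})
            elif isinstance(item, Mapping):
                records.append(dict(item))
            else:
                raise TypeError(f"cannot report item of type {type(item).__name__}")
        frame = pd.DataFrame.from_records(records)
        if len(frame.columns):
            frame = frame.sort_values(by=list(frame.columns[:1]), kind="mergesort")
        frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
        return
    raise TypeError(f"cannot report object of type {type(result).__name__}")
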