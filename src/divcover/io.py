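"""Readers and writers for the on-disk artifacts of the pipeline.

Sequences travel as FASTA (alignments as gapped FASTA), per-record
metadata as a tab-separated table, and trees as Newick.  All readers
validate strictly: duplicate identifiers, empty sequences, non-IUPAC
characters and malformed metadata are hard errors, never warnings.

On ingest every sequence is upper-cased, ``U`` is normalised to ``T``
and IUPAC ambiguity codes other than A/C/G/T are collapsed to ``N`` so
that downstream identity and entropy computations see a five-letter
alphabet (plus ``-`` inside alignments).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "SOURCES",
    "SeqRecord",
    "Alignment",
    "MetadataRow",
    "read_fasta",
    "write_fasta",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "read_metadata",
    "write_metadata",
    "attach_metadata",
]

#: Valid values of the per-record ``source`` tag.  ``reference`` marks
#: database exports, ``genome`` marks rRNA genes predicted from genome
#: assemblies, ``collection`` marks culture-collection strains.
SOURCES = ("reference", "genome", "collection")

_IUPAC = set("ACGTUNRYSWKMBDHV")
_AMBIG_TO_N = str.maketrans({c: "N" for c in "RYSWKMBDHV"})


def _clean_sequence(raw: str, record_id: str, *, allow_gaps: bool = False) -> str:
    """Normalise a raw nucleotide string (upper-case, U->T, ambiguity->N)."""
    seq = raw.upper()
    alphabet = _IUPAC | ({"-"} if allow_gaps else set())
    for pos, ch in enumerate(seq):
        if ch not in alphabet:
            raise ValueError(
                f"record {record_id!r}: non-IUPAC character {ch!r} at position {pos}"
            )
    if not allow_gaps and not seq:
        raise ValueError(f"record {record_id!r}: empty sequence")
    return seq.replace("U", "T").translate(_AMBIG_TO_N)


@dataclass(frozen=True)
class SeqRecord:
    """One rRNA sequence plus its study metadata.

    ``source`` is ``None`` until metadata has been attached; once set it
    must be one of :data:`SOURCES`.  ``genome_accession`` may only be
    present on genome-source records.
    """

    id: str
    sequence: str
    source: str | None = None
    lineage: tuple[str, ...] = ()
    genome_accession: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.source is not None and self.source not in SOURCES:
            raise ValueError(f"record {self.id!r}: unknown source {self.source!r}")
        if self.genome_accession is not None and self.source != "genome":
            raise ValueError(
                f"record {self.id!r}: genome_accession implies source='genome'"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MetadataRow:
    id: str
    source: str
    lineage: tuple[str, ...]
    genome_accession: str | None


@dataclass
class Alignment:
    """A rectangular gapped character matrix over record identifiers."""

    ids: list[str]
    matrix: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.matrix):
            raise ValueError("ids and matrix rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row identifiers in alignment")
        if self.matrix:
            width = len(self.matrix[0])
            for rid, row in zip(self.ids, self.matrix):
                if len(row) != width:
                    raise ValueError(
                        f"row {rid!r} has length {len(row)}, expected {width}"
                    )
                if set(row) <= {"-"}:
                    raise ValueError(f"row {rid!r} is all-gap")

    @property
    def column_count(self) -> int:
        return len(self.matrix[0]) if self.matrix else 0

    @property
    def row_count(self) -> int:
        return len(self.ids)

    def row(self, rid: str) -> str:
        return self.matrix[self.ids.index(rid)]

    def subset_rows(self, keep_ids: Sequence[str]) -> "Alignment":
        """Rows restricted to ``keep_ids``, in the given order."""
        index = {rid: i for i, rid in enumerate(self.ids)}
        missing = [rid for rid in keep_ids if rid not in index]
        if missing:
            raise KeyError(f"rows absent from alignment: {missing}")
        return Alignment(
            ids=list(keep_ids), matrix=[self.matrix[index[r]] for r in keep_ids]
        )

    def missing_fraction(self) -> float:
        """Fraction of cells that are gaps or N (the missing-data metric)."""
        cells = self.row_count * self.column_count
        if cells == 0:
            return 0.0
        missing = sum(row.count("-") + row.count("N") for row in self.matrix)
        return missing / cells


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read ungapped sequences; gap characters are rejected."""
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise ValueError(f"duplicate identifier {rid!r} in {path}")
        seen.add(rid)
        raw = str(entry.seq)
        if "-" in raw:
            raise ValueError(f"record {rid!r}: gap character in unaligned FASTA")
        records.append(SeqRecord(id=rid, sequence=_clean_sequence(raw, rid)))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_alignment_fasta(path: str | Path) -> Alignment:
    ids: list[str] = []
    rows: list[str] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise ValueError(f"duplicate identifier {rid!r} in {path}")
        seen.add(rid)
        ids.append(rid)
        rows.append(_clean_sequence(str(entry.seq), rid, allow_gaps=True))
    return Alignment(ids=ids, matrix=rows)


def write_alignment_fasta(alignment: Alignment, path: str | Path, width: int = 70) -> None:
    with open(path, "w", newline="\n") as fh:
        for rid, row in zip(alignment.ids, alignment.matrix):
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


_META_COLUMNS = ("id", "source", "lineage", "genome_accession")


def read_metadata(path: str | Path) -> dict[str, MetadataRow]:
    """Read the tab-separated metadata table keyed by record id.

    Columns: ``id``, ``source``, ``lineage`` (semicolon-delimited ranks,
    may be empty) and ``genome_accession`` (may be empty).
    """
    import pandas as pd

    frame = pd.read_csv(str(path), sep="\t", dtype=str, keep_default_na=False)
    got = tuple(frame.columns)
    if got != _META_COLUMNS:
        raise ValueError(f"metadata columns {got} != expected {_META_COLUMNS}")
    rows: dict[str, MetadataRow] = {}
    for rec in frame.itertuples(index=False):
        if rec.id in rows:
            raise ValueError(f"duplicate metadata id {rec.id!r}")
        if rec.source not in SOURCES:
            raise ValueError(
                f"metadata id {rec.id!r}: unknown source {rec.source!r} "
                f"(expected one of {SOURCES})"
            )
        lineage = tuple(
            part.strip() for part in rec.lineage.split(";") if part.strip()
        )
        accession = rec.genome_accession or None
        if accession is not None and rec.source != "genome":
            raise ValueError(
                f"metadata id {rec.id!r}: genome_accession set on source "
                f"{rec.source!r}"
            )
        rows[rec.id] = MetadataRow(rec.id, rec.source, lineage, accession)
    return rows


def write_metadata(rows: Iterable[MetadataRow], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(_META_COLUMNS) + "\n")
        for row in rows:
            fh.write(
                f"{row.id}\t{row.source}\t{';'.join(row.lineage)}\t"
                f"{row.genome_accession or ''}\n"
            )


def attach_metadata(
    records: Sequence[SeqRecord],
    metadata: Mapping[str, MetadataRow],
    *,
    allow_orphan_genomes: bool = False,
) -> tuple[list[SeqRecord], list[str]]:
    """Join metadata onto records; the join must be total on both sides.

    Returns the annotated records plus the list of metadata ids with no
    sequence.  Orphan metadata rows are a hard error unless they are
    genome-source rows and ``allow_orphan_genomes`` is set (an assembly
    may legitimately have no predicted rRNA gene; the caller logs it).
    """
    annotated: list[SeqRecord] = []
    missing_meta = [rec.id for rec in records if rec.id not in metadata]
    if missing_meta:
        raise ValueError(f"records with no metadata row: {missing_meta}")
    record_ids = {rec.id for rec in records}
    orphans = [rid for rid in metadata if rid not in record_ids]
    bad_orphans = [
        rid for rid in orphans if not (allow_orphan_genomes and metadata[rid].source == "genome")
    ]
    if bad_orphans:
        raise ValueError(f"metadata ids with no sequence: {bad_orphans}")
    for rec in records:
        row = metadata[rec.id]
        annotated.append(
            replace(
                rec,
                source=row.source,
                lineage=row.lineage,
                genome_accession=row.genome_accession,
            )
        )
    return annotated, orphans
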