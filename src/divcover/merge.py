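"""Merge the three tagged rRNA sources into one accounted dataset.

Two filters run before concatenation:

* a lineage-congruence filter — a record whose asserted lineage names
  neither the expected ingroup clade nor any explicitly allowed clade
  (typically the outgroup) is dropped, emulating the manual deletion of
  database sequences mis-lineaged into a foreign phylum.  Records with
  an empty lineage are trusted and kept (culture-collection strains
  usually carry no database lineage).
* a genome-usability filter — genome-source records with an off-clade
  lineage are dropped, and genome accessions present in the metadata
  but with no rRNA sequence at all are logged; both mirror the
  exclusion of assemblies without usable rRNA genes.

Every removal is logged in a :class:`MergeReport` whose counts satisfy
``n_output == sum(inputs) - n_removed_incongruent -
n_removed_unusable_genomes`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import MetadataRow, SeqRecord

__all__ = [
    "MergeReport",
    "filter_incongruent",
    "drop_unusable_genomes",
    "merge_sources",
    "write_merge_report",
]


@dataclass
class MergeReport:
    n_input_per_source: dict[str, int]
    n_removed_incongruent: int
    n_removed_unusable_genomes: int
    n_output: int
    removed_ids: list[tuple[str, str]]
    #: genome accessions in the metadata with no sequence at all
    #: (logged, never subtracted: they were never input records)
    no_rrna_genome_ids: list[str] = field(default_factory=list)

    def check(self) -> None:
        total_in = sum(self.n_input_per_source.values())
        expected = total_in - self.n_removed_incongruent - self.n_removed_unusable_genomes
        if self.n_output != expected:
            raise AssertionError(
                f"merge accounting broken: {self.n_output} != {expected}"
            )
        ids = [rid for rid, _ in self.removed_ids]
        if len(ids) != len(set(ids)):
            raise AssertionError("a removed id was logged twice")


def _is_congruent(
    lineage: Sequence[str], allowed: frozenset[str]
) -> bool:
    return not lineage or bool(allowed.intersection(lineage))


def filter_incongruent(
    records: Sequence[SeqRecord],
    expected_root: str,
    allowed_clades: Iterable[str] = (),
) -> tuple[list[SeqRecord], list[str]]:
    """Drop records whose non-empty lineage misses every allowed clade."""
    allowed = frozenset({expected_root, *allowed_clades})
    kept: list[SeqRecord] = []
    removed: list[str] = []
    for rec in records:
        if _is_congruent(rec.lineage, allowed):
            kept.append(rec)
        else:
            removed.append(rec.id)
    return kept, removed


def drop_unusable_genomes(
    records: Sequence[SeqRecord],
    metadata: Mapping[str, MetadataRow] | None,
    expected_root: str,
    allowed_clades: Iterable[str] = (),
) -> tuple[list[SeqRecord], list[tuple[str, str]], list[str]]:
    """Apply the genome-usability rule to genome-source records.

    Returns ``(kept, removed, no_rrna_ids)``: genome records with an
    off-clade lineage are removed with reason ``"non-target rRNA"``;
    metadata genome rows with no sequence are listed as
    ``no_rrna_ids`` ("no rRNA predicted") without touching the record
    set.  Non-genome records pass through untouched.
    """
    allowed = frozenset({expected_root, *allowed_clades})
    kept: list[SeqRecord] = []
    removed: list[tuple[str, str]] = []
    for rec in records:
        if rec.source == "genome" and not _is_congruent(rec.lineage, allowed):
            removed.append((rec.id, "non-target rRNA"))
        else:
            kept.append(rec)
    no_rrna: list[str] = []
    if metadata is not None:
        present = {rec.id for rec in records}
        no_rrna = [
            rid
            for rid, row in metadata.items()
            if row.source == "genome" and rid not in present
        ]
    return kept, removed, no_rrna


def merge_sources(
    reference: Sequence[SeqRecord],
    genome: Sequence[SeqRecord],
    collection: Sequence[SeqRecord],
    expected_root: str,
    allowed_clades: Iterable[str] = (),
    metadata: Mapping[str, MetadataRow] | None = None,
) -> tuple[list[SeqRecord], MergeReport]:
    """Concatenate the three sources after both filters, with accounting."""
    all_ids = [r.id for recs in (reference, genome, collection) for r in recs]
    if len(all_ids) != len(set(all_ids)):
        dupes = sorted({i for i in all_ids if all_ids.count(i) > 1})
        raise ValueError(f"id collision across sources: {dupes}")

    n_input = {
        "reference": len(reference),
        "genome": len(genome),
        "collection": len(collection),
    }
    genome_kept, genome_removed, no_rrna = drop_unusable_genomes(
        genome, metadata, expected_root, allowed_clades
    )
    candidates = list(reference) + genome_kept + list(collection)
    kept, incongruent_ids = filter_incongruent(
        candidates, expected_root, allowed_clades
    )
    removed = [(rid, "incongruent lineage") for rid in incongruent_ids]
    removed += genome_removed
    report = MergeReport(
        n_input_per_source=n_input,
        n_removed_incongruent=len(incongruent_ids),
        n_removed_unusable_genomes=len(genome_removed),
        n_output=len(kept),
        removed_ids=removed,
        no_rrna_genome_ids=no_rrna,
    )
    report.check()
    return kept, report


def write_merge_report(report: MergeReport, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("key\tvalue\n")
        for source, count in sorted(report.n_input_per_source.items()):
            fh.write(f"n_input_{source}\t{count}\n")
        fh.write(f"n_removed_incongruent\t{report.n_removed_incongruent}\n")
        fh.write(
            f"n_removed_unusable_genomes\t{report.n_removed_unusable_genomes}\n"
        )
        fh.write(f"n_output\t{report.n_output}\n")
        for rid, reason in report.removed_ids:
            fh.write(f"removed\t{rid} ({reason})\n")
        for rid in report.no_rrna_genome_ids:
            fh.write(f"no_rrna_predicted\t{rid}\n")
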