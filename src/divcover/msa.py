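"""Seed-alignment extension and entropy/gap column trimming.

``extend_alignment`` threads new ungapped sequences into a curated seed
multiple alignment without ever touching the seed's rows or column
count: each new sequence is globally aligned (same scoring as the
dereplication step) against the seed's majority-rule consensus and its
residues are dropped into the corresponding seed columns.  Insertions
relative to the seed are discarded rather than opening new columns —
a sparse novel column would fail the gap cut-off downstream anyway.

``trim_alignment`` is a per-column filter in the BMGE spirit: a column
is kept iff its normalised Shannon entropy (log-base-4, computed over
A/C/G/T only) is at or below the entropy cut-off and its gap fraction
is at or below the gap cut-off.  No window smoothing or minimum block
size is applied, so the operation is order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._align import align_stats, make_aligner
from .io import Alignment, SeqRecord

__all__ = [
    "ColumnScore",
    "TrimResult",
    "consensus",
    "extend_alignment",
    "score_columns",
    "trim_alignment",
]

_CODE = {c: i for i, c in enumerate("ACGTN-")}


def _matrix_codes(alignment: Alignment) -> np.ndarray:
    raw = np.frombuffer("".join(alignment.matrix).encode(), dtype=np.uint8)
    codes = np.zeros(raw.shape, dtype=np.uint8)
    for ch, code in _CODE.items():
        codes[raw == ord(ch)] = code
    return codes.reshape(alignment.row_count, alignment.column_count)


def consensus(alignment: Alignment) -> str:
    """Majority-rule consensus with gap as a fifth state.

    A column whose gap fraction exceeds 50% (or that has no A/C/G/T at
    all) gets a consensus gap; otherwise the most frequent base wins,
    ties broken alphabetically.
    """
    codes = _matrix_codes(alignment)
    rows = codes.shape[0]
    out = []
    for col in codes.T:
        gaps = int(np.count_nonzero(col == _CODE["-"]))
        counts = [int(np.count_nonzero(col == b)) for b in range(4)]
        if gaps * 2 > rows or sum(counts) == 0:
            out.append("-")
        else:
            out.append("ACGT"[int(np.argmax(counts))])
    return "".join(out)


def extend_alignment(
    seed: Alignment,
    new_records: Sequence[SeqRecord],
    min_placed: float = 0.5,
) -> tuple[Alignment, list[tuple[str, str]]]:
    """Add new sequences to the seed alignment, seed columns untouched.

    Returns the extended alignment (seed rows first, byte-identical to
    the input) and a skip report of ``(id, reason)`` for sequences with
    fewer than ``min_placed`` of their residues placeable.
    """
    overlap = set(seed.ids) & {rec.id for rec in new_records}
    if overlap:
        raise ValueError(f"new record ids already in seed: {sorted(overlap)}")
    cons = consensus(seed)
    base_columns = [i for i, ch in enumerate(cons) if ch != "-"]
    cons_seq = "".join(cons[i] for i in base_columns)
    if not cons_seq:
        raise ValueError("seed consensus is all-gap; cannot extend")
    aligner = make_aligner()
    ids = list(seed.ids)
    rows = list(seed.matrix)
    skipped: list[tuple[str, str]] = []
    for rec in new_records:
        if "-" in rec.sequence:
            raise ValueError(f"record {rec.id!r}: new sequences must be gap-free")
        _, _, _, blocks = align_stats(cons_seq, rec.sequence, aligner)
        row = ["-"] * seed.column_count
        placed = 0
        for (s1, e1), (s2, e2) in zip(blocks[0], blocks[1]):
            for k in range(e1 - s1):
                row[base_columns[s1 + k]] = rec.sequence[s2 + k]
                placed += 1
        if placed < min_placed * len(rec.sequence):
            skipped.append(
                (rec.id, f"only {placed}/{len(rec.sequence)} residues placeable")
            )
            continue
        ids.append(rec.id)
        rows.append("".join(row))
    return Alignment(ids=ids, matrix=rows), skipped


@dataclass(frozen=True)
class ColumnScore:
    entropy: float
    gap_fraction: float
    kept: bool


def score_columns(
    alignment: Alignment,
    entropy_cutoff: float = 0.5,
    gap_cutoff: float = 0.2,
) -> list[ColumnScore]:
    """Per-column normalised entropy and gap fraction.

    Entropy is Shannon entropy of the observed A/C/G/T frequencies
    divided by log 4, so it lives in [0, 1]; N and '-' are excluded
    from the entropy but '-' counts toward the gap fraction.  Columns
    with no bases at all score entropy 1.0 (maximally uninformative).
    """
    codes = _matrix_codes(alignment)
    rows = codes.shape[0]
    scores: list[ColumnScore] = []
    for col in codes.T:
        counts = np.array([np.count_nonzero(col == b) for b in range(4)], dtype=float)
        total = counts.sum()
        if total == 0:
            entropy = 1.0
        else:
            p = counts[counts > 0] / total
            entropy = float(-(p * np.log(p)).sum() / math.log(4.0))
        gap_fraction = float(np.count_nonzero(col == _CODE["-"]) / rows)
        kept = entropy <= entropy_cutoff and gap_fraction <= gap_cutoff
        scores.append(ColumnScore(entropy=entropy, gap_fraction=gap_fraction, kept=kept))
    return scores


@dataclass
class TrimResult:
    alignment: Alignment
    kept_columns: list[int]
    dropped_rows: list[str]
    #: gaps+N over cells of the trimmed alignment — the missing
    #: character states metric reported for curated alignments
    missing_fraction: float


def trim_alignment(
    alignment: Alignment,
    entropy_cutoff: float = 0.5,
    gap_cutoff: float = 0.2,
) -> TrimResult:
    """Keep exactly the columns passing both cut-offs, in order."""
    scores = score_columns(alignment, entropy_cutoff, gap_cutoff)
    kept = [i for i, s in enumerate(scores) if s.kept]
    if not kept:
        raise ValueError("no conserved sites: every column failed the cut-offs")
    ids: list[str] = []
    rows: list[str] = []
    dropped: list[str] = []
    for rid, row in zip(alignment.ids, alignment.matrix):
        new_row = "".join(row[i] for i in kept)
        if set(new_row) <= {"-"}:
            dropped.append(rid)
        else:
            ids.append(rid)
            rows.append(new_row)
    trimmed = Alignment(ids=ids, matrix=rows)
    return TrimResult(
        alignment=trimmed,
        kept_columns=kept,
        dropped_rows=dropped,
        missing_fraction=trimmed.missing_fraction(),
    )
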