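"""Jukes-Cantor pairwise distances from a trimmed alignment.

Sites are compared under pairwise deletion: a pair of rows is compared
only at columns where both carry a plain base (A/C/G/T).  The JC69
correction d = -(3/4) ln(1 - (4/3) p) diverges as the mismatch
fraction p approaches 3/4, so saturated pairs (p >= 0.75) are capped
at :data:`SATURATION_CAP` to keep the matrix finite.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix

from .io import Alignment

__all__ = ["SATURATION_CAP", "jc_distance", "distance_matrix", "write_phylip"]

SATURATION_CAP = 5.0

_BASES = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(row: str) -> np.ndarray:
    raw = np.frombuffer(row.encode(), dtype=np.uint8)
    out = np.full(raw.shape, 255, dtype=np.uint8)
    for ch, code in _BASES.items():
        out[raw == ord(ch)] = code
    return out


def _jc_from_codes(a: np.ndarray, b: np.ndarray, label: str) -> float:
    both = (a != 255) & (b != 255)
    compared = int(np.count_nonzero(both))
    if compared == 0:
        raise ValueError(f"no overlapping ungapped columns for pair {label}")
    p = int(np.count_nonzero((a != b) & both)) / compared
    if p >= 0.75:
        return SATURATION_CAP
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def jc_distance(row_a: str, row_b: str) -> float:
    """JC69 distance between two equal-length gapped rows."""
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    return _jc_from_codes(_encode(row_a), _encode(row_b), "(a, b)")


def distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """All-pairs JC distances; symmetric with a zero diagonal."""
    if alignment.row_count < 3:
        raise ValueError("need at least 3 rows for a distance matrix")
    codes = [_encode(row) for row in alignment.matrix]
    n = alignment.row_count
    data = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            label = f"({alignment.ids[i]}, {alignment.ids[j]})"
            data[i, j] = data[j, i] = _jc_from_codes(codes[i], codes[j], label)
    return DistanceMatrix(data, ids=list(alignment.ids))


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP distance matrix, for interoperability."""
    with open(path, "w", newline="\n") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for rid, row in zip(dm.ids, dm.data):
            fh.write(rid + "  " + "  ".join(f"{v:.8f}" for v in row) + "\n")
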