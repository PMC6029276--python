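"""Shared global pairwise alignment with end-gap-free scoring.

One scoring scheme is pinned for the whole package: match +1,
mismatch -1, gap open -2, gap extension -1, terminal gaps free, and N
scoring as a mismatch against everything (including N), so that an
ambiguous base can never contribute to identity.
"""

from __future__ import annotations

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = ["make_aligner", "align_stats"]

_ALPHABET = "ACGTN"


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    scores = np.full((5, 5), -1.0)
    for i in range(4):  # N (index 4) stays -1 everywhere
        scores[i, i] = 1.0
    aligner.substitution_matrix = substitution_matrices.Array(
        _ALPHABET, dims=2, data=scores
    )
    aligner.mode = "global"
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -1.0
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def align_stats(
    a: str, b: str, aligner: Align.PairwiseAligner
) -> tuple[int, tuple[int, int], tuple[int, int], np.ndarray]:
    """Align ``a`` against ``b`` and summarise the first optimal alignment.

    Returns ``(n_identical, span_a, span_b, blocks)`` where each span is
    the (start, end) of the aligned (non-terminal-gap) region on that
    sequence and ``blocks`` is the pair of aligned coordinate blocks.
    """
    alignment = aligner.align(a, b)[0]
    blocks = alignment.aligned
    if blocks.shape[1] == 0:
        return 0, (0, 0), (0, 0), blocks
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    n_code = ord("N")
    identical = 0
    for (s1, e1), (s2, e2) in zip(blocks[0], blocks[1]):
        seg_a = xa[s1:e1]
        seg_b = xb[s2:e2]
        identical += int(np.count_nonzero((seg_a == seg_b) & (seg_a != n_code)))
    span_a = (int(blocks[0][0][0]), int(blocks[0][-1][1]))
    span_b = (int(blocks[1][0][0]), int(blocks[1][-1][1]))
    return identical, span_a, span_b, blocks
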