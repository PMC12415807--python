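"""Semi-global (overlap) pairwise alignment.

End-gap-free alignment with unit costs: match +1, mismatch −1, gap −1; gaps
at either end of either sequence are free.  This is the classic overlap
alignment used to compare an amplicon against a reference fragment when
neither is expected to contain the other exactly.

Identity is matches / aligned columns with gap columns counted as
mismatching, and query coverage is the fraction of query bases inside the
aligned region — the two quantities reference-database searches threshold on
(e.g. 97% identity, 100% query coverage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequtils import iupac_masks

MATCH = 1
MISMATCH = -1
GAP = -1


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of one pairwise overlap alignment."""

    identity: float  # matches / aligned columns, gaps count as mismatches
    coverage: float  # aligned query bases / query length
    score: int
    subject_id: str | None = None
    matches: int = 0
    columns: int = 0

    def __post_init__(self) -> None:
        assert 0.0 <= self.identity <= 1.0
        assert 0.0 <= self.coverage <= 1.0


def _score_matrix(query: str, subject: str) -> np.ndarray:
    """Dynamic-programming table; row/col 0 are free (zero) end gaps."""
    qm = iupac_masks(query).astype(np.int64)
    sm = iupac_masks(subject).astype(np.int64)
    n, m = len(qm), len(sm)
    # substitution scores, IUPAC-aware: intersecting base sets count as match
    sub = np.where((qm[:, None] & sm[None, :]) != 0, MATCH, MISMATCH)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    ar = np.arange(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        # best of diagonal / vertical-gap moves per column
        d = np.empty(m + 1, dtype=np.int64)
        d[0] = 0  # free leading gap column
        np.maximum(H[i - 1, :-1] + sub[i - 1], H[i - 1, 1:] + GAP, out=d[1:])
        # fold in horizontal gap chains with a prefix max:
        # H[i,j] = max_{k<=j} d[k] - (j-k)*|GAP|
        H[i] = np.maximum.accumulate(d + ar) - ar
    return H


def align_semiglobal(query: str, subject: str, subject_id: str | None = None) -> AlignmentResult:
    """Overlap-align ``query`` against ``subject``.

    Deterministic: ambiguous tracebacks prefer diagonal, then vertical, then
    horizontal moves; the alignment end is the highest-scoring cell on the
    last row or column, ties resolved toward consuming more of the query.
    """
    if not query or not subject:
        raise ValueError("align_semiglobal requires non-empty sequences")
    qm = iupac_masks(query)
    sm = iupac_masks(subject)
    n, m = len(query), len(subject)
    H = _score_matrix(query, subject)

    # best end cell: last row and last column are valid alignment ends
    j_best = int(np.argmax(H[n]))
    i_best = int(np.argmax(H[:, m]))
    if H[i_best, m] > H[n, j_best]:
        i, j = i_best, m
    else:
        i, j = n, j_best
    score = int(H[i, j])

    matches = columns = 0
    i_end = i
    while i > 0 and j > 0:
        hit = (qm[i - 1] & sm[j - 1]) != 0
        sub = MATCH if hit else MISMATCH
        if H[i, j] == H[i - 1, j - 1] + sub:
            matches += int(hit)
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + GAP:
            i -= 1
        else:
            j -= 1
        columns += 1
    q_aligned = i_end - i
    identity = matches / columns if columns else 0.0
    coverage = q_aligned / n
    return AlignmentResult(identity, coverage, score, subject_id, matches, columns)
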