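"""Semiglobal pairwise alignment of amplicon reads against the reference.

Reads (and candidate allele sequences) are aligned end-to-end against a
contiguous segment of the reference: terminal reference overhangs are free,
terminal query overhangs are penalized like internal gaps.  Affine gap
costs are used, with a gap of length ``k`` scoring
``gap_open + k * gap_extend``.

The heavy lifting is done by :class:`Bio.Align.PairwiseAligner`; this module
wraps it with the scoring convention above, a deterministic choice among
co-optimal alignments, and a fast gapless path for equal-length reads whose
optimality is provable from the scoring bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align

from .reference import validate_dna

__all__ = ["Scoring", "AlignmentResult", "semiglobal_align", "DEFAULT_SCORING"]


@dataclass(frozen=True)
class Scoring:
    """Alignment scores; a length-k gap costs ``gap_open + k * gap_extend``."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -1.0

    def gap_cost(self, length: int) -> float:
        return self.gap_open + length * self.gap_extend

    def max_score(self, query_length: int) -> float:
        return self.match * query_length


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class AlignmentResult:
    """An aligned query/reference pair with terminal overhangs trimmed.

    ``aligned_query`` and ``aligned_ref`` are equal-length gapped strings
    covering reference positions ``ref_start .. ref_end`` (1-based,
    inclusive).  ``score`` is the semiglobal score of the full alignment
    (reference overhangs contribute zero).
    """

    aligned_query: str
    aligned_ref: str
    score: float
    ref_start: int
    ref_end: int

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_ref):
            raise ValueError("aligned strings must have equal length")


@lru_cache(maxsize=8)
def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # Biopython charges open for the first gap base and extend thereafter;
    # our convention charges open + extend for the first base.
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    # Free end gaps on the query row <=> unpenalized reference overhangs.
    try:
        aligner.end_deletion_score = 0.0
    except (AttributeError, ValueError):  # pragma: no cover - older Biopython
        aligner.query_end_gap_score = 0.0
    return aligner


def _gapless_result(query: str, ref: str, scoring: Scoring) -> AlignmentResult:
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    mismatches = int((q != r).sum())
    score = scoring.match * (len(query) - mismatches) + scoring.mismatch * mismatches
    return AlignmentResult(query, ref, score, 1, len(ref))


def _gapless_is_optimal(query: str, ref: str, scoring: Scoring) -> bool:
    """True when the gapless alignment of equal-length sequences is provably
    optimal: any alignment containing a gap sacrifices at least one match and
    pays at least one gap-open, so it can beat at most a bounded number of
    mismatches."""
    if len(query) != len(ref):
        return False
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    mismatches = int((q != r).sum())
    # gapless score: 2L - 5m (defaults); best gapped score <= 2(L-1) - 6.
    gapless = scoring.match * len(query) + (scoring.mismatch - scoring.match) * mismatches
    gapped_bound = (
        scoring.match * (len(query) - 1) + scoring.gap_cost(1)
    )
    return gapless >= gapped_bound


def semiglobal_align(
    query: str, ref: str, scoring: Scoring = DEFAULT_SCORING
) -> AlignmentResult:
    """Align ``query`` end-to-end against a contiguous segment of ``ref``.

    Terminal reference overhangs are unpenalized; the query itself is always
    fully aligned.  Among co-optimal alignments the first one enumerated by
    the aligner is returned — downstream indel calls are left-normalized, so
    the tie-break never changes a reported mutation.

    Raises
    ------
    InvalidSequenceError
        If either input is empty or contains non-ACGT characters.
    """
    validate_dna(query, "query")
    validate_dna(ref, "reference")
    if len(query) == len(ref) and _gapless_is_optimal(query, ref, scoring):
        return _gapless_result(query, ref, scoring)

    aligner = _make_aligner(scoring)
    alignment = aligner.align(ref, query)[0]
    aligned_ref = str(alignment[0])
    aligned_query = str(alignment[1])

    # Trim terminal reference-overhang columns (gaps in the query row).
    n = len(aligned_query)
    lo = 0
    while lo < n and aligned_query[lo] == "-":
        lo += 1
    hi = n
    while hi > lo and aligned_query[hi - 1] == "-":
        hi -= 1
    ref_start = 1 + sum(1 for c in aligned_ref[:lo] if c != "-")
    ref_consumed = sum(1 for c in aligned_ref[lo:hi] if c != "-")
    ref_end = ref_start + ref_consumed - 1
    return AlignmentResult(
        aligned_query[lo:hi],
        aligned_ref[lo:hi],
        float(alignment.score),
        ref_start,
        ref_end,
    )
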