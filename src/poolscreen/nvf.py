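"""Nucleotide-variant-frequency (NVF) screening of pooled amplicon libraries.

The NVF at a reference position is the fraction of aligned reads whose base
differs from the reference there: a mismatch, a base inside a read deletion,
or (by convention) the left-anchor base of a read insertion.  A pool
containing a mutant shows elevated NVF across the edited positions; diluting
the pool's PCR product 1:6 with wild-type product reduces a true mutation's
NVF roughly seven-fold while leaving the sequencing-error background
unchanged.  That contrast — elevation over the error baseline combined with
reduction on dilution — is the pool-level mutation call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .align import DEFAULT_SCORING, Scoring, semiglobal_align
from .mutations import calls_from_alignment, left_normalize
from .reference import ReferenceAmplicon
from .simulate import ReadSet

__all__ = [
    "NVFProfile",
    "Baseline",
    "DilutionPair",
    "CallParams",
    "PoolCall",
    "compute_nvf",
    "estimate_baseline",
    "dilution_contrast_call",
    "summarize_screen",
]

# En dash for printed position ranges.
_DASH = "–"


@dataclass(frozen=True)
class NVFProfile:
    """Per-position coverage and variant counts over the scored window."""

    positions: np.ndarray  # 1-based reference positions
    coverage: np.ndarray
    variant_count: np.ndarray
    ref_id: str
    window: tuple[int, int]
    n_reads: int
    n_failed_qc: int

    def __post_init__(self) -> None:
        if np.any(self.coverage <= 0):
            raise ValueError("NVF is undefined at zero-coverage positions")
        if np.any(self.variant_count > self.coverage):
            raise ValueError("variant count exceeds coverage")

    @property
    def nvf(self) -> np.ndarray:
        return self.variant_count / self.coverage

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "coverage": self.coverage,
                "variant_count": self.variant_count,
                "nvf": self.nvf,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Baseline:
    """Wild-type error NVF per position with binomial dispersion."""

    profile: NVFProfile
    low_coverage: bool

    @property
    def nvf(self) -> np.ndarray:
        return self.profile.nvf

    @property
    def sd(self) -> np.ndarray:
        p = self.profile.nvf
        return np.sqrt(np.maximum(p * (1 - p), 0) / self.profile.coverage)


@dataclass(frozen=True)
class DilutionPair:
    """Undiluted and diluted NVF profiles of the same pool."""

    undiluted: NVFProfile
    diluted: NVFProfile
    factor: float = 6.0

    def __post_init__(self) -> None:
        if (
            self.undiluted.window != self.diluted.window
            or self.undiluted.ref_id != self.diluted.ref_id
        ):
            raise ValueError("profiles differ in window or reference")


@dataclass(frozen=True)
class CallParams:
    """Thresholds of the three-condition position flagging rule.

    A position is flagged when (a) its undiluted variant count exceeds the
    wild-type baseline by a one-sided binomial test at ``alpha``
    Bonferroni-corrected over the window, (b) the undiluted NVF is at least
    ``floor``, and (c) the diluted NVF is at most ``rho`` times the
    undiluted NVF (the expectation under a true mutation is about
    ``1/(1+factor)`` plus the error floor, i.e. well below ``rho``).
    """

    alpha: float = 0.05
    floor: float = 0.005
    rho: float = 0.6


@dataclass(frozen=True)
class PoolCall:
    """The pool-level decision with per-position evidence."""

    pool_id: str
    positive: bool
    flagged_positions: tuple[int, ...]
    locus_interval: tuple[int, int] | None
    evidence: pd.DataFrame = field(repr=False)

    @property
    def locus_text(self) -> str:
        if self.locus_interval is None:
            return "None detected"
        lo, hi = self.locus_interval
        if lo == hi:
            return f"Nucleotide position {lo}"
        return f"Nucleotide positions {lo}{_DASH}{hi}"


class EmptyReadSetError(ValueError):
    pass


@lru_cache(maxsize=120_000)
def _read_events(
    seq: str, ref_seq: str, scoring: Scoring, min_score_frac: float
) -> tuple[bool, int, int, tuple[int, ...]]:
    """Per unique read: (passed_qc, ref_start, ref_end, variant positions).

    Indels are left-normalized before counting so that homology-ambiguous
    placements register at the same (leftmost) positions as the published
    convention.
    """
    aln = semiglobal_align(seq, ref_seq, scoring)
    if aln.score < min_score_frac * scoring.max_score(len(seq)):
        return (False, 0, 0, ())
    positions: set[int] = set()
    for call in calls_from_alignment(aln):
        if call.kind != "substitution":
            call = left_normalize(call, ref_seq)
        positions.update(call.variant_positions())
    return (True, aln.ref_start, aln.ref_end, tuple(sorted(positions)))


def _iter_counts(reads) -> Iterable[tuple[str, int]]:
    if isinstance(reads, ReadSet):
        return reads.sequences()
    if hasattr(reads, "items") and not isinstance(reads, (list, tuple)):
        return reads.items()
    from collections import Counter

    return Counter(reads).items()


def compute_nvf(
    reads,
    ref: ReferenceAmplicon,
    scoring: Scoring = DEFAULT_SCORING,
    min_score_frac: float = 0.6,
) -> NVFProfile:
    """Compute the per-position NVF profile of a read set over the window.

    ``reads`` may be a :class:`ReadSet`, a mapping of sequence to count, or
    an iterable of sequences.  Reads whose alignment score falls below
    ``min_score_frac`` of the maximum possible are excluded and tallied in
    ``n_failed_qc``.
    """
    L = ref.length
    coverage = np.zeros(L + 2, dtype=np.int64)  # diff array for spans
    variant = np.zeros(L + 1, dtype=np.int64)
    n_reads = 0
    n_failed = 0
    items = list(_iter_counts(reads))
    if not items:
        raise EmptyReadSetError("cannot compute an NVF profile from zero reads")
    for seq, count in items:
        n_reads += count
        ok, start, end, positions = _read_events(
            seq, ref.sequence, scoring, min_score_frac
        )
        if not ok:
            n_failed += count
            continue
        coverage[start] += count
        coverage[end + 1] -= count
        for p in positions:
            if 1 <= p <= L:
                variant[p] += count
    cov = np.cumsum(coverage)[1 : L + 1]
    lo, hi = ref.target_window
    window_positions = np.arange(lo, hi + 1)
    return NVFProfile(
        positions=window_positions,
        coverage=cov[lo - 1 : hi],
        variant_count=variant[lo : hi + 1],
        ref_id=ref.id,
        window=ref.target_window,
        n_reads=n_reads,
        n_failed_qc=n_failed,
    )


def estimate_baseline(
    wt_reads,
    ref: ReferenceAmplicon,
    coverage_floor: int = 1_000,
    scoring: Scoring = DEFAULT_SCORING,
) -> Baseline:
    """Per-position error NVF from a wild-type-only control library.

    Coverage below ``coverage_floor`` is flagged (the baseline is then too
    noisy to anchor the binomial test reliably)."""
    profile = compute_nvf(wt_reads, ref, scoring)
    low = bool(np.any(profile.coverage < coverage_floor))
    if low:
        import warnings

        warnings.warn(
            f"wild-type control coverage below {coverage_floor}x; "
            "baseline estimates will be noisy",
            stacklevel=2,
        )
    return Baseline(profile=profile, low_coverage=low)


def dilution_contrast_call(
    pair: DilutionPair,
    baseline: Baseline,
    params: CallParams = CallParams(),
    pool_id: str | None = None,
) -> PoolCall:
    """Call a pool by the elevated-then-reduced-on-dilution criterion.

    The pool is positive iff at least one window position passes all three
    conditions of :class:`CallParams`; the locus interval is the min..max of
    flagged positions.
    """
    u, d = pair.undiluted, pair.diluted
    if baseline.profile.window != u.window:
        raise ValueError("baseline window differs from the pool profiles")
    positions = u.positions
    n_positions = positions.size
    p0 = np.maximum(baseline.nvf, 1e-6)
    # one-sided binomial upper tail: P(X >= k | n, p0)
    pvalues = binom.sf(u.variant_count - 1, u.coverage, p0)
    alpha_corrected = params.alpha / n_positions
    nvf_u = u.nvf
    nvf_d = d.nvf
    flagged = (
        (pvalues < alpha_corrected)
        & (nvf_u >= params.floor)
        & (nvf_d <= params.rho * nvf_u)
    )
    flagged_positions = tuple(int(p) for p in positions[flagged])
    positive = bool(flagged.any())
    evidence = pd.DataFrame(
        {
            "position": positions,
            "coverage_u": u.coverage,
            "nvf_u": nvf_u,
            "coverage_d": d.coverage,
            "nvf_d": nvf_d,
            "baseline": baseline.nvf,
            "p_value": pvalues,
            "flagged": flagged,
        }
    )
    return PoolCall(
        pool_id=pool_id or "pool",
        positive=positive,
        flagged_positions=flagged_positions,
        locus_interval=(
            (flagged_positions[0], flagged_positions[-1]) if positive else None
        ),
        evidence=evidence,
    )


def summarize_screen(
    calls: Sequence[PoolCall],
    truth: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Tabulate pool calls (and accuracy against unsealed truth if given)."""
    rows = []
    for call in calls:
        row = {
            "pool_id": call.pool_id,
            "positive": call.positive,
            "locus": call.locus_text,
        }
        if truth is not None:
            expected = truth[call.pool_id]
            row["truth"] = expected
            row["correct"] = expected == call.positive
        rows.append(row)
    return pd.DataFrame(rows)
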