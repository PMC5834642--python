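"""Indel calls, leftmost normalization and human-readable mutation text.

A CRISPR-induced edit is represented as an :class:`IndelCall` in 1-based
reference coordinates.  Deletions are reported as the closed interval of
deleted bases; an insertion is anchored by the position its first inserted
base assumes when written into the reference numbering (i.e. the call
``insertion @ position p`` inserts immediately before reference position
``p``).  Flanking sequence homology can make several placements of the same
edit indistinguishable at the sequence level; calls are normalized to the
leftmost placement and carry the full interval of equivalent start
positions, which is rendered as e.g. ``"1 bp insertion @ position 51 or 52
(T)"`` when wider than one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .align import DEFAULT_SCORING, AlignmentResult, Scoring, semiglobal_align
from .reference import (
    CONTEXT_END,
    CONTEXT_START,
    ReferenceAmplicon,
    validate_dna,
)

__all__ = [
    "CallError",
    "IndelCall",
    "MutationDescription",
    "COMPLEX_ALLELE",
    "apply_mutation",
    "apply_calls",
    "left_normalize",
    "calls_from_alignment",
    "describe_allele",
    "describe_window_allele",
]

_KINDS = ("deletion", "insertion", "substitution")

# En dash, as used in the printed range descriptions ("positions 45-49").
_DASH = "–"


class CallError(ValueError):
    """Raised when an indel call is inconsistent with the reference."""


@dataclass(frozen=True)
class IndelCall:
    """A normalized edit in 1-based reference coordinates.

    ``start``/``end`` delimit deleted bases for deletions; for insertions
    ``start == end`` is the position assumed by the first inserted base
    (insertion immediately before reference position ``start``); for
    substitutions ``start == end`` is the replaced base and ``inserted`` the
    replacement.  ``ambiguity`` is the closed interval of equivalent start
    positions under flanking homology and always contains ``start``.
    """

    kind: str
    length: int
    start: int
    end: int
    inserted: str = ""
    ambiguity: tuple[int, int] = field(default=(0, 0))

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise CallError(f"unknown call kind {self.kind!r}")
        if self.length < 1:
            raise CallError("call length must be >= 1")
        if self.start < 1 or self.end < self.start:
            raise CallError(f"invalid interval {self.start}..{self.end}")
        if self.kind == "deletion":
            if self.end - self.start + 1 != self.length:
                raise CallError("deletion interval does not match its length")
            if self.inserted:
                raise CallError("deletions carry no inserted bases")
        else:
            if self.start != self.end:
                raise CallError(f"{self.kind} must have start == end")
            validate_dna(self.inserted, "inserted bases")
            if len(self.inserted) != self.length:
                raise CallError(f"{self.kind} length does not match its bases")
        amb = self.ambiguity if self.ambiguity != (0, 0) else (self.start, self.start)
        object.__setattr__(self, "ambiguity", amb)
        lo, hi = self.ambiguity
        if not lo <= self.start <= hi:
            raise CallError("ambiguity interval must contain the start position")

    @property
    def is_ambiguous(self) -> bool:
        return self.ambiguity[0] != self.ambiguity[1]

    def variant_positions(self) -> range:
        """Reference positions at which this call registers as a variant.

        Deletions count at every deleted base; an insertion counts at its
        left-anchor base (the reference base immediately 5' of the insertion
        point); a substitution at the substituted base.
        """
        if self.kind == "deletion":
            return range(self.start, self.end + 1)
        if self.kind == "insertion":
            anchor = max(1, self.start - 1)
            return range(anchor, anchor + 1)
        return range(self.start, self.end + 1)

    def description(self) -> str:
        """Render the call in the conventional phrasing."""
        if self.kind == "deletion":
            if self.length == 1:
                where = f"position {self.start}"
            elif self.length == 2:
                where = f"positions {self.start} and {self.end}"
            else:
                where = f"positions {self.start}{_DASH}{self.end}"
            return f"{self.length} bp deletion @ {where}"
        if self.kind == "insertion":
            lo, hi = self.ambiguity
            where = f"position {lo}" if lo == hi else f"position {lo} or {hi}"
            return f"{self.length} bp insertion @ {where} ({self.inserted})"
        return f"{self.length} bp substitution @ position {self.start} ({self.inserted})"

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "length": self.length,
                "start": self.start,
                "end": self.end,
                "inserted": self.inserted,
                "ambiguity": list(self.ambiguity),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "IndelCall":
        d = json.loads(text)
        return cls(
            kind=d["kind"],
            length=d["length"],
            start=d["start"],
            end=d["end"],
            inserted=d.get("inserted", ""),
            ambiguity=tuple(d.get("ambiguity", (0, 0))),
        )


@dataclass(frozen=True)
class MutationDescription:
    """A rendered mutation: the normalized call plus its display text.

    ``call`` is ``None`` for the sentinel complex-allele result."""

    text: str
    call: IndelCall | None = None

    @property
    def is_complex(self) -> bool:
        return self.call is None

    def to_json(self) -> str:
        return json.dumps(
            {"text": self.text, "call": None if self.call is None else json.loads(self.call.to_json())}
        )


#: Sentinel returned when an allele cannot be explained by a small number of
#: simple edits.
COMPLEX_ALLELE = MutationDescription(text="complex allele", call=None)


def apply_mutation(ref: str, call: IndelCall) -> str:
    """Apply a single call to a reference string, returning the mutant.

    Raises :class:`CallError` for out-of-range positions or substitutions
    identical to the reference base.
    """
    validate_dna(ref, "reference")
    if call.kind == "insertion":
        if not 1 <= call.start <= len(ref) + 1:
            raise CallError(f"insertion point {call.start} outside reference")
        return ref[: call.start - 1] + call.inserted + ref[call.start - 1 :]
    if call.end > len(ref):
        raise CallError(f"call interval {call.start}..{call.end} outside reference")
    if call.kind == "deletion":
        return ref[: call.start - 1] + ref[call.end :]
    # substitution
    if ref[call.start - 1 : call.end] == call.inserted:
        raise CallError("substitution is identical to the reference")
    return ref[: call.start - 1] + call.inserted + ref[call.end :]


def apply_calls(ref: str, calls: Iterable[IndelCall]) -> str:
    """Apply non-overlapping calls, right to left so coordinates stay valid."""
    out = ref
    for call in sorted(calls, key=lambda c: c.start, reverse=True):
        out = apply_mutation(out, call)
    return out


def left_normalize(call: IndelCall, ref: str) -> IndelCall:
    """Shift an indel to its leftmost equivalent placement.

    The ambiguity interval spans every start position whose placement yields
    the same mutated sequence.  Substitutions are returned unchanged (with a
    width-1 ambiguity).  Idempotent.
    """
    validate_dna(ref, "reference")
    if call.kind == "substitution":
        if call.end > len(ref):
            raise CallError("substitution outside reference")
        if ref[call.start - 1 : call.end] == call.inserted:
            raise CallError("substitution is identical to the reference")
        return replace(call, ambiguity=(call.start, call.start))

    if call.kind == "deletion":
        if call.end > len(ref):
            raise CallError("deletion outside reference")
        s, e = call.start, call.end
        # deleting [s-1, e-1] is equivalent iff ref[s-1] == ref[e]
        while s > 1 and ref[s - 2] == ref[e - 1]:
            s -= 1
            e -= 1
        lo = s
        s, e = call.start, call.end
        while e < len(ref) and ref[s - 1] == ref[e]:
            s += 1
            e += 1
        hi = s
        return replace(
            call, start=lo, end=lo + call.length - 1, ambiguity=(lo, hi)
        )

    # insertion: inserting X before p equals inserting rot(X) before p-1
    # iff the last inserted base matches ref[p-2].
    if not 1 <= call.start <= len(ref) + 1:
        raise CallError("insertion point outside reference")
    p, bases = call.start, call.inserted
    while p > 1 and bases[-1] == ref[p - 2]:
        bases = ref[p - 2] + bases[:-1]
        p -= 1
    lo, lo_bases = p, bases
    p, bases = call.start, call.inserted
    while p <= len(ref) and bases[0] == ref[p - 1]:
        bases = bases[1:] + ref[p - 1]
        p += 1
    hi = p
    return replace(
        call, start=lo, end=lo, inserted=lo_bases, ambiguity=(lo, hi)
    )


def calls_from_alignment(aln: AlignmentResult) -> list[IndelCall]:
    """Extract raw (un-normalized) calls from an aligned query/ref pair.

    Gap runs become single indel events; each mismatched column becomes a
    1-bp substitution.  Positions are global 1-based reference coordinates.
    """
    calls: list[IndelCall] = []
    ref_pos = aln.ref_start  # position of the next reference base
    i = 0
    q, r = aln.aligned_query, aln.aligned_ref
    n = len(q)
    while i < n:
        if q[i] == "-":  # deletion: reference bases absent from the query
            j = i
            while j < n and q[j] == "-":
                j += 1
            length = j - i
            calls.append(
                IndelCall(
                    kind="deletion",
                    length=length,
                    start=ref_pos,
                    end=ref_pos + length - 1,
                )
            )
            ref_pos += length
            i = j
        elif r[i] == "-":  # insertion before the next reference base
            j = i
            while j < n and r[j] == "-":
                j += 1
            inserted = q[i:j]
            calls.append(
                IndelCall(
                    kind="insertion",
                    length=len(inserted),
                    start=ref_pos,
                    end=ref_pos,
                    inserted=inserted,
                )
            )
            i = j
        else:
            if q[i] != r[i]:
                calls.append(
                    IndelCall(
                        kind="substitution",
                        length=1,
                        start=ref_pos,
                        end=ref_pos,
                        inserted=q[i],
                    )
                )
            ref_pos += 1
            i += 1
    return calls


def _ref_sequence(ref: ReferenceAmplicon | str) -> str:
    return ref.sequence if isinstance(ref, ReferenceAmplicon) else ref


def describe_allele(
    allele: str,
    ref: ReferenceAmplicon | str,
    scoring: Scoring = DEFAULT_SCORING,
    max_indels: int = 2,
    max_substitutions: int = 2,
) -> list[MutationDescription]:
    """Describe an allele as a list of normalized mutation descriptions.

    Returns an empty list iff the allele equals the reference.  An allele
    requiring more than ``max_indels`` indels or ``max_substitutions``
    substitutions is reported as the single :data:`COMPLEX_ALLELE` sentinel
    rather than as a possibly wrong simple call.
    """
    ref_seq = _ref_sequence(ref)
    validate_dna(allele, "allele")
    if allele == ref_seq:
        return []
    aln = semiglobal_align(allele, ref_seq, scoring)
    raw = calls_from_alignment(aln)
    n_indels = sum(1 for c in raw if c.kind != "substitution")
    n_subs = sum(1 for c in raw if c.kind == "substitution")
    if n_indels > max_indels or n_subs > max_substitutions:
        return [COMPLEX_ALLELE]
    normalized = [left_normalize(c, ref_seq) for c in raw]
    normalized.sort(key=lambda c: (c.start, c.kind))
    return [MutationDescription(text=c.description(), call=c) for c in normalized]


def describe_window_allele(
    window_allele: str,
    ref: ReferenceAmplicon,
    window: tuple[int, int] = (CONTEXT_START, CONTEXT_END),
    **kwargs,
) -> list[MutationDescription]:
    """Describe a printed window-level allele (e.g. ``"AAAGATGAGATG"``).

    Published mutation tables print only the edited window; the wild-type
    sequence continues on both flanks.  The window string is therefore
    implanted between the reference flanks before description — aligning the
    bare fragment on its own would let it drift to spurious placements.
    """
    validate_dna(window_allele, "window allele")
    lo, hi = window
    full = ref.sequence[: lo - 1] + window_allele + ref.sequence[hi:]
    return describe_allele(full, ref, **kwargs)
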