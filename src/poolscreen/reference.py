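"""Reference amplicon model and the packaged synthetic 186-bp PDS target.

The screen works on a single PCR amplicon spanning the sgRNA target site in
the fourth exon of the tobacco phytoene desaturase (*PDS*) gene.  The true
genomic sequence of that amplicon is not public; what is constrained is

* its length (186 bp, delimited by the PDS-F / PDS-R primers),
* the wild-type sequence ``AAAGATGATGATG`` at 1-based positions 43-55 (the
  region in which all reported indels fall), and
* a ``TGG`` PAM immediately 3' of that mutation cluster, so the canonical
  Cas9 cut site (3 bp 5' of the PAM) lies inside the observed indel cluster.

The packaged :data:`REFERENCE` therefore places the primers at the ends, the
printed context at 43-55 and the PAM at 56-58, and fills the remaining bases
deterministically from a fixed seed (the resulting sequence is frozen below).
All coordinates throughout the package are 1-based and inclusive, matching
the convention of the published mutation descriptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "DNA_ALPHABET",
    "InvalidSequenceError",
    "ReferenceAmplicon",
    "REFERENCE",
    "WT_CONTEXT",
    "CONTEXT_START",
    "CONTEXT_END",
    "CUT_SITE",
    "reverse_complement",
    "validate_dna",
]

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class InvalidSequenceError(ValueError):
    """Raised when a sequence is empty or contains non-ACGT characters."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a plus-strand DNA string."""
    validate_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, name: str = "sequence") -> None:
    """Reject empty strings and anything outside the A/C/G/T alphabet."""
    if not isinstance(seq, str) or not seq:
        raise InvalidSequenceError(f"{name} must be a non-empty DNA string")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise InvalidSequenceError(
            f"{name} contains non-ACGT characters: {sorted(bad)!r}"
        )


@dataclass(frozen=True)
class ReferenceAmplicon:
    """A reference amplicon with 1-based inclusive coordinates.

    Parameters
    ----------
    id:
        FASTA identifier, preserved verbatim on round trips.
    sequence:
        Plus-strand sequence, A/C/G/T only.
    target_window:
        ``(start, end)`` interval over which per-position variant
        frequencies are scored (77 bp wide by default, centred on the cut
        site of the packaged reference).
    pam:
        Optional ``(start, end, strand)`` annotation of the PAM.
    """

    id: str
    sequence: str
    target_window: tuple[int, int]
    pam: tuple[int, int, str] | None = field(default=None)

    def __post_init__(self) -> None:
        validate_dna(self.sequence, "reference sequence")
        start, end = self.target_window
        if not (1 <= start <= end <= len(self.sequence)):
            raise ValueError(
                f"target window {self.target_window} outside amplicon of "
                f"length {len(self.sequence)}"
            )
        if self.pam is not None:
            ps, pe, strand = self.pam
            if not (1 <= ps <= pe <= len(self.sequence)) or strand not in "+-":
                raise ValueError(f"invalid PAM annotation {self.pam!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def window_positions(self) -> range:
        """1-based positions of the scored window (inclusive)."""
        return range(self.target_window[0], self.target_window[1] + 1)

    def base(self, position: int) -> str:
        """Base at a 1-based position."""
        if not 1 <= position <= self.length:
            raise ValueError(f"position {position} outside 1..{self.length}")
        return self.sequence[position - 1]

    def region(self, start: int, end: int) -> str:
        """Subsequence over a 1-based inclusive interval."""
        if not (1 <= start <= end <= self.length):
            raise ValueError(f"region {start}-{end} outside 1..{self.length}")
        return self.sequence[start - 1 : end]


#: Wild-type sequence at positions 43-55 in which the indel cluster lies.
WT_CONTEXT = "AAAGATGATGATG"
CONTEXT_START = 43
CONTEXT_END = 55

#: First base 3' of the blunt Cas9 cut (3 nt upstream of the TGG PAM).
CUT_SITE = 53

# Frozen synthetic amplicon: PDS-F primer (1-18), seeded filler (19-42),
# WT context (43-55), TGG PAM (56-58), seeded filler (59-165),
# reverse complement of PDS-R (166-186).  Construction constraints: the
# context occurs exactly once, no homopolymer of >= 6 bp, and position 98
# is not an ``A`` so that the long deletion spanning 51-98 left-normalizes
# to its printed start.
REFERENCE_SEQUENCE = (
    "CTGAAGCAGTCACCAAGATGGCCAAAATGTGGTGGGGTCTGAAAAGATGATGATGTGGCTGATGTAA"
    "TAGACCCCAAAAGGGCGTCCTTTCGTGTGGCTAGGTGCCCCGTATGCGGCCGGGCTCCTCAGGAACT"
    "CTCATTAAGCGATCTTGATAGCTATAGGTCTGACTCCTCAAGAATGCGTACT"
)

#: The packaged reference amplicon used throughout the package and tests.
REFERENCE = ReferenceAmplicon(
    id="pds_amplicon_186",
    sequence=REFERENCE_SEQUENCE,
    target_window=(14, 90),
    pam=(56, 58, "+"),
)

assert len(REFERENCE_SEQUENCE) == 186
assert REFERENCE.region(CONTEXT_START, CONTEXT_END) == WT_CONTEXT
assert REFERENCE.region(56, 58) == "TGG"
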