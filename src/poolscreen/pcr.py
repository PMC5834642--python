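"""In-silico PCR and the three-primer-set transgene presence assay.

A mutant plant is scored non-transgenic when none of three primer sets
targeting distinct regions of the CRISPR/Cas9 T-DNA (left-border/35S
junction, Cas9 3' end, kanamycin-resistance gene) yields a product from its
genomic DNA.  Primer matching is deliberately strict by default: no
mismatches, and the 3'-terminal base of each primer must pair exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import yaml

from .plants import PlantGenotype
from .reference import reverse_complement, validate_dna

__all__ = [
    "PrimerSet",
    "PCRProduct",
    "ConfigurationError",
    "in_silico_pcr",
    "classify_transgene",
    "genome_sequences",
    "synthetic_tdna_regions",
    "load_primer_sets",
    "dump_primer_sets",
    "PDS_PRIMERS",
    "TDNA_PRIMER_SETS",
]


class ConfigurationError(ValueError):
    """Raised for malformed primer-set configuration."""


@dataclass(frozen=True)
class PrimerSet:
    """A forward/reverse primer pair with an optional expected product size."""

    name: str
    forward: str
    reverse: str
    expected_size: int | None = None
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        validate_dna(self.forward, f"{self.name} forward primer")
        validate_dna(self.reverse, f"{self.name} reverse primer")
        if self.max_mismatch < 0:
            raise ConfigurationError("max_mismatch must be >= 0")
        if self.expected_size is not None and self.expected_size <= len(
            self.forward
        ) + len(self.reverse):
            raise ConfigurationError(
                f"{self.name}: expected_size must exceed the combined primer length"
            )


@dataclass(frozen=True)
class PCRProduct:
    """A predicted amplicon: 1-based inclusive template coordinates."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _site_matches(template: str, site: str, max_mismatch: int, exact_index: int) -> list[int]:
    """0-based template offsets where ``site`` matches within ``max_mismatch``
    mismatches, with the base at ``exact_index`` (within the site) exact."""
    n, m = len(template), len(site)
    if m > n:
        return []
    t = np.frombuffer(template.encode(), dtype=np.uint8)
    s = np.frombuffer(site.encode(), dtype=np.uint8)
    # sliding-window mismatch counts
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    mismatches = (windows != s).sum(axis=1)
    ok = mismatches <= max_mismatch
    if max_mismatch > 0:
        ok &= windows[:, exact_index] == s[exact_index]
    return list(np.nonzero(ok)[0])


def in_silico_pcr(
    template: str,
    primers: PrimerSet,
    max_product_size: int = 10_000,
) -> list[PCRProduct]:
    """Predict amplicons of a primer pair on a plus-strand template.

    A product is reported when the forward primer matches the plus strand
    and the reverse complement of the reverse primer matches downstream,
    each within ``primers.max_mismatch`` mismatches (3'-terminal bases must
    always pair exactly).  An empty list means no product.
    """
    validate_dna(template, "template")
    fwd_sites = _site_matches(
        template, primers.forward, primers.max_mismatch, len(primers.forward) - 1
    )
    rev_site = reverse_complement(primers.reverse)
    # the reverse primer's 3' terminus corresponds to the first base of the
    # plus-strand site
    rev_sites = _site_matches(template, rev_site, primers.max_mismatch, 0)
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            end = r + len(rev_site)  # exclusive
            length = end - f
            if length >= len(primers.forward) + len(rev_site) and length <= max_product_size:
                products.append(PCRProduct(start=f + 1, end=end))
    return sorted(products, key=lambda p: (p.start, p.end))


def classify_transgene(
    genome: Sequence[str],
    primer_sets: Sequence[PrimerSet],
) -> str:
    """Classify a plant as ``"transgenic"`` or ``"non-transgenic"``.

    ``genome`` is the collection of sequences representing the plant's
    genomic DNA (target alleles plus any integrated T-DNA segments).  A
    plant is non-transgenic iff all three primer sets yield no product from
    any sequence.
    """
    if len(primer_sets) != 3:
        raise ConfigurationError(
            f"transgene classification requires exactly 3 primer sets, got {len(primer_sets)}"
        )
    for seq in genome:
        for primers in primer_sets:
            if in_silico_pcr(seq, primers):
                return "transgenic"
    return "non-transgenic"


# ---------------------------------------------------------------------------
# primer definitions
# ---------------------------------------------------------------------------

#: Primers delimiting the 186-bp PDS target amplicon.
PDS_PRIMERS = PrimerSet(
    name="PDS",
    forward="CTGAAGCAGTCACCAAGA",
    reverse="AGTACGCATTCTTGAGGAGTC",
    expected_size=186,
)

#: The three T-DNA primer sets with their expected product sizes.
TDNA_PRIMER_SETS = (
    PrimerSet(
        name="set1_border_35s",
        forward="AGGTGGCGAAGTCATCTGC",
        reverse="TGTCGTTTCCCGCCTTCAG",
        expected_size=701,
    ),
    PrimerSet(
        name="set2_cas9",
        forward="GCCTGTTTGGTAATCTTATCGC",
        reverse="TCTTTCCACTCTGCTTGTCTCG",
        expected_size=1326,
    ),
    PrimerSet(
        name="set3_kanr",
        forward="ACTGGGCACAACAGACAATC",
        reverse="ACCGTAAAGCACGAGGAA",
        expected_size=668,
    ),
)

_TDNA_REGION_BY_PRIMERS = {
    "border_35s": TDNA_PRIMER_SETS[0],
    "cas9": TDNA_PRIMER_SETS[1],
    "kanr": TDNA_PRIMER_SETS[2],
}


def synthetic_tdna_regions(seed: int = 20180302) -> dict[str, str]:
    """Synthetic stand-ins for the three T-DNA regions.

    The true vector sequence is not packaged; each synthetic region embeds
    its primer pair at the documented product size (701, 1326 and 668 bp)
    inside seeded random filler, which is all the transgene assay observes.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    regions: dict[str, str] = {}
    for region, primers in _TDNA_REGION_BY_PRIMERS.items():
        size = primers.expected_size
        assert size is not None
        fwd = primers.forward
        rev_site = reverse_complement(primers.reverse)
        filler_len = size - len(fwd) - len(rev_site)
        while True:
            filler = "".join(rng.choice(bases, filler_len))
            pad5 = "".join(rng.choice(bases, 30))
            pad3 = "".join(rng.choice(bases, 30))
            seq = pad5 + fwd + filler + rev_site + pad3
            if len(in_silico_pcr(seq, primers)) == 1:
                regions[region] = seq
                break
    return regions


def genome_sequences(
    genotype: PlantGenotype,
    tdna_regions: dict[str, str] | None = None,
) -> list[str]:
    """Sequences representing a plant's genomic DNA for the PCR assay:
    its four target alleles plus any T-DNA regions flagged present."""
    if tdna_regions is None:
        tdna_regions = synthetic_tdna_regions()
    seqs = list(genotype.alleles)
    for region, present in genotype.tdna.as_dict().items():
        if present:
            seqs.append(tdna_regions[region])
    return seqs


# ---------------------------------------------------------------------------
# YAML interface
# ---------------------------------------------------------------------------

def load_primer_sets(path) -> list[PrimerSet]:
    """Load primer sets from a YAML file (list of mappings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ConfigurationError("primer YAML must contain a list of primer sets")
    out = []
    for entry in raw:
        out.append(
            PrimerSet(
                name=str(entry["name"]),
                forward=str(entry["forward"]),
                reverse=str(entry["reverse"]),
                expected_size=entry.get("expected_size"),
                max_mismatch=int(entry.get("max_mismatch", 0)),
            )
        )
    return out


def dump_primer_sets(primer_sets: Iterable[PrimerSet], path) -> None:
    data = [
        {
            "name": p.name,
            "forward": p.forward,
            "reverse": p.reverse,
            "expected_size": p.expected_size,
            "max_mismatch": p.max_mismatch,
        }
        for p in primer_sets
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
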