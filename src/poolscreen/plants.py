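"""Tetraploid plant genotypes and their T-DNA integration status."""

from __future__ import annotations

from dataclasses import dataclass, field

from .mutations import IndelCall
from .reference import ReferenceAmplicon, validate_dna

__all__ = ["TDNAStatus", "PlantGenotype", "wild_type_genotype"]

#: Names of the three T-DNA regions interrogated by the transgene PCR assay:
#: the left-border/35S promoter junction, the 3' end of the Cas9 coding
#: sequence, and the kanamycin-resistance gene.
TDNA_REGIONS = ("border_35s", "cas9", "kanr")


@dataclass(frozen=True)
class TDNAStatus:
    """Presence flags for the three assayed T-DNA regions."""

    border_35s: bool = False
    cas9: bool = False
    kanr: bool = False

    @property
    def any_present(self) -> bool:
        return self.border_35s or self.cas9 or self.kanr

    def as_dict(self) -> dict[str, bool]:
        return {
            "border_35s": self.border_35s,
            "cas9": self.cas9,
            "kanr": self.kanr,
        }


@dataclass(frozen=True)
class PlantGenotype:
    """A tetraploid plant: exactly four alleles of the target amplicon.

    ``allele_calls[i]`` holds the normalized edits of ``alleles[i]``; an
    empty tuple marks a wild-type allele.
    """

    plant_id: str
    alleles: tuple[str, str, str, str]
    allele_calls: tuple[tuple[IndelCall, ...], ...]
    tdna: TDNAStatus = field(default_factory=TDNAStatus)

    def __post_init__(self) -> None:
        if len(self.alleles) != 4:
            raise ValueError("a tetraploid genotype has exactly 4 alleles")
        if len(self.allele_calls) != 4:
            raise ValueError("allele_calls must have one entry per allele")
        for a in self.alleles:
            validate_dna(a, "allele")

    @property
    def is_wild_type(self) -> bool:
        return all(len(calls) == 0 for calls in self.allele_calls)

    @property
    def is_tetra_allelic_mutant(self) -> bool:
        """True when no allele is wild type."""
        return all(len(calls) > 0 for calls in self.allele_calls)

    @property
    def n_mutant_alleles(self) -> int:
        return sum(1 for calls in self.allele_calls if calls)

    def truth_variant_positions(
        self, window: tuple[int, int] | None = None
    ) -> tuple[int, ...]:
        """Union of per-allele variant positions, optionally window-clipped."""
        positions: set[int] = set()
        for calls in self.allele_calls:
            for call in calls:
                positions.update(call.variant_positions())
        if window is not None:
            lo, hi = window
            positions = {p for p in positions if lo <= p <= hi}
        return tuple(sorted(positions))


def wild_type_genotype(plant_id: str, ref: ReferenceAmplicon) -> PlantGenotype:
    """A plant carrying four reference alleles and no T-DNA."""
    return PlantGenotype(
        plant_id=plant_id,
        alleles=(ref.sequence,) * 4,
        allele_calls=((), (), (), ()),
        tdna=TDNAStatus(),
    )
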