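import numpy as np
import pytest

from poolscreen import (
    REFERENCE,
    IndelCall,
    PlantGenotype,
    apply_mutation,
    left_normalize,
    wild_type_genotype,
)

#: The published per-line mutation table: window allele (gap-free) and its
#: printed description, for every distinct in-window allele.
TABLE2_CASES = [
    # pds-9
    ("AAAGATGAGATG", "1 bp deletion @ position 51"),
    ("AAAGATGATTGATG", "1 bp insertion @ position 51 or 52 (T)"),
    ("AAAGATTG", "5 bp deletion @ positions 49–53"),
    ("AAAGATGGATG", "2 bp deletion @ positions 50 and 51"),
    # pds-10
    ("AAAGATTGATG", "2 bp deletion @ positions 49 and 50"),
    ("AAAGATGAATG", "2 bp deletion @ positions 51 and 52"),
    # pds-11 (first three alleles; the fourth extends past the window)
    ("AAAGATGAGTGATG", "1 bp insertion @ position 51 (G)"),
    # pds-12
    ("AAATGATG", "5 bp deletion @ positions 45–49"),
    ("AAAATGATG", "4 bp deletion @ positions 46–49"),
    # pds-13
    ("AAAGATATGATG", "1 bp deletion @ position 49"),
    ("AAAGATGTGATG", "1 bp deletion @ position 50"),
    ("AATGATG", "6 bp deletion @ positions 44–49"),
    ("AAAGATGAATGATG", "1 bp insertion @ position 50 or 51 (A)"),
    # pds-14
    ("AAAGATG", "6 bp deletion @ positions 46–51"),
]

#: The four alleles of the line whose pooled screen is shown in detail
#: (pds-12): calls in reference coordinates.
PDS12_CALLS = (
    IndelCall("deletion", 1, 51, 51),
    IndelCall("deletion", 5, 45, 49),
    IndelCall("deletion", 2, 49, 50),
    IndelCall("deletion", 4, 46, 49),
)


def genotype_from_calls(plant_id, calls, ref=REFERENCE, tdna=None) -> PlantGenotype:
    """Build a tetraploid genotype carrying one given call per allele."""
    kwargs = {} if tdna is None else {"tdna": tdna}
    return PlantGenotype(
        plant_id=plant_id,
        alleles=tuple(apply_mutation(ref.sequence, c) for c in calls),
        allele_calls=tuple((left_normalize(c, ref.sequence),) for c in calls),
        **kwargs,
    )


@pytest.fixture(scope="session")
def ref():
    return REFERENCE


@pytest.fixture(scope="session")
def wt_genotype():
    return wild_type_genotype("WT", REFERENCE)


@pytest.fixture(scope="session")
def pds12_genotype():
    return genotype_from_calls("pds-12", PDS12_CALLS)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
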