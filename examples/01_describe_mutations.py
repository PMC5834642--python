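"""Describe CRISPR alleles against the packaged 186-bp PDS amplicon.

Mutant alleles are aligned to the reference, indels are shifted to their
leftmost equivalent placement (reporting the homology-ambiguity interval),
and rendered in the conventional phrasing, e.g.
"1 bp insertion @ position 51 or 52 (T)".
"""

from poolscreen import REFERENCE, IndelCall, apply_mutation, describe_allele
from poolscreen.mutations import describe_window_allele

# Window-level alleles as a sequencing report would print them (the
# wild-type context AAAGATGATGATG occupies positions 43-55).
window_alleles = [
    "AAAGATGAGATG",    # one base missing
    "AAAGATGATTGATG",  # one base gained inside the TG repeat
    "AAATGATG",        # five bases missing, placement ambiguous
    "AAAGATG",         # six bases missing
]

print("window allele      description")
for allele in window_alleles:
    (desc,) = describe_window_allele(allele, REFERENCE)
    print(f"{allele:<18} {desc.text}")

# Full-length alleles round-trip: applying a call and re-describing it
# recovers the normalized call.
call = IndelCall("insertion", 1, 52, 52, inserted="T")
allele = apply_mutation(REFERENCE.sequence, call)
(desc,) = describe_allele(allele, REFERENCE)
print("\nround trip:", desc.text)
print("equivalent insertion points (homology):", desc.call.ambiguity)
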