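"""Classify mutants as transgenic vs non-transgenic by in-silico PCR.

A plant is non-transgenic when none of three primer sets targeting distinct
T-DNA regions (left-border/35S junction, Cas9 3' end, kanamycin-resistance
gene) yields a product from its genomic DNA.  The expected product sizes
are 701, 1326 and 668 bp.
"""

from poolscreen import (
    REFERENCE,
    TDNA_PRIMER_SETS,
    classify_transgene,
    genome_sequences,
    in_silico_pcr,
    simulate_mutant_genotype,
    synthetic_tdna_regions,
)

regions = synthetic_tdna_regions()

transgenic = simulate_mutant_genotype(seed=1, plant_id="escape", transgenic=True)
clean = simulate_mutant_genotype(seed=2, plant_id="keeper", transgenic=False)

for plant in (transgenic, clean):
    genome = genome_sequences(plant, regions)
    status = classify_transgene(genome, TDNA_PRIMER_SETS)
    print(f"{plant.plant_id}: {status}")
    for primers in TDNA_PRIMER_SETS:
        products = [
            int(p.length) for seq in genome for p in in_silico_pcr(seq, primers)
        ]
        print(f"   {primers.name:<16} products: {products or 'none'}")
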