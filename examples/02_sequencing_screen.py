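"""Stage 1: pooled amplicon sequencing with the x6 dilution contrast.

Simulates a 42-plant pool (one tetra-allelic mutant + 41 wild type) at
20,000x coverage with realistic sequencing error, dilutes its PCR product
1:6 with wild-type product, and calls the pool from the per-position
nucleotide variant frequencies (NVF): a position is flagged when its NVF is
elevated over the wild-type error baseline AND drops on dilution.
"""

from poolscreen import (
    REFERENCE,
    DilutionPair,
    ErrorModel,
    compute_nvf,
    dilute_reads,
    dilution_contrast_call,
    estimate_baseline,
    simulate_mutant_genotype,
    simulate_pool_reads,
    wild_type_genotype,
)
from poolscreen.simulate import PoolSpec

error = ErrorModel()  # substitution 0.003/bp, indel 0.0005/bp
mutant = simulate_mutant_genotype(seed=4, plant_id="mutant")
wt = wild_type_genotype("WT", REFERENCE)
genotypes = {"mutant": mutant, "WT": wt}

print("true edits in the hidden mutant:")
for calls in mutant.allele_calls:
    print("  ", calls[0].description())

pool = PoolSpec("pool", ("mutant",) + ("WT",) * 41)
undiluted = simulate_pool_reads(pool, genotypes, error, coverage=20_000, seed=1)
wt_source = simulate_pool_reads(
    PoolSpec("wt84", ("WT",) * 84), genotypes, error, coverage=20_000, seed=2
)
wt_control = simulate_pool_reads(
    PoolSpec("ctl", ("WT",) * 84), genotypes, error, coverage=20_000, seed=3
)
diluted = dilute_reads(undiluted, wt_source, factor=6, seed=4)

baseline = estimate_baseline(wt_control, REFERENCE)
pair = DilutionPair(
    compute_nvf(undiluted, REFERENCE), compute_nvf(diluted, REFERENCE)
)
call = dilution_contrast_call(pair, baseline, pool_id="pool")

print("\npool positive:", call.positive)
print("mutant locus:", call.locus_text)
truth = mutant.truth_variant_positions(REFERENCE.target_window)
print("generator truth span:", (min(truth), max(truth)))
ev = call.evidence
locus = ev[ev.flagged]
print("\nflagged positions (NVF before vs after dilution vs WT baseline):")
print(
    locus[["position", "nvf_u", "nvf_d", "baseline"]]
    .round(4)
    .to_string(index=False)
)
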