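# poolscreen

Pooled screening for CRISPR/Cas9-edited, **non-transgenic** plants.

When Cas9 and its sgRNA are expressed only transiently (no antibiotic
selection), most regenerated shoots carry neither an edit nor the T-DNA —
so the problem becomes finding a handful of edited plants among hundreds of
unselected shoots, and then discarding the edited plants that *did* pick up
the transgene. `poolscreen` implements a desk version of a two-step
group-testing protocol for exactly this, developed around a tetraploid
tobacco *PDS* (phytoene desaturase) amplicon:

1. **Sequencing stage (42-plant pools).** A 186-bp amplicon spanning the
   sgRNA target is deep-sequenced per pool. For each reference position
   *i* the **nucleotide variant frequency** is

   NVF(i) = (reads not matching the reference at *i*) / coverage(i),

   counting mismatches, deleted bases, and insertion left-anchors. A pool's
   PCR product is also re-sequenced after mixing with **6×** wild-type
   product: a true mutation's NVF falls to ≈ NVF/7 while sequencing-error
   NVF is unchanged. A position is flagged when
   (a) its variant count beats the wild-type baseline by a one-sided
   binomial test (Bonferroni-corrected over the 77-position window),
   (b) NVF ≥ 0.005, and (c) NVF_diluted ≤ 0.6 · NVF_undiluted.
2. **HRM stage (7-plant pools, then 1:1).** Positive pools are split into
   7-plant pools genotyped by high-resolution melting: mutant/wild-type
   heteroduplexes melt ~2 °C early, deforming the normalized melt curve.
   A pool is positive when max |ΔRFU| against a wild-type reference exceeds
   5× the median replicate SD. Individual mutants are confirmed by HRM of a
   1:1 mix with a wild-type plant.
3. **Transgene assay.** Confirmed mutants are classified non-transgenic iff
   three primer sets targeting distinct T-DNA regions (expected products
   701, 1326, 668 bp) all yield nothing in silico.

Every input is synthesizable: the package ships generators for tetraploid
tetra-allelic genotypes (indels drawn from the observed mutation spectrum),
pooled amplicon reads with substitution/indel error, ×6-diluted libraries,
triplicate melt curves with homo-/heteroduplex structure, and single-blind
pool sets with sealed truth manifests — so the whole screen runs and is
tested without any sequencing data.

## Worked example

```python
from poolscreen import *
from poolscreen.simulate import PoolSpec

error = ErrorModel()                      # substitution 3e-3, indel 5e-4 per bp
mutant = simulate_mutant_genotype(seed=4, plant_id="mutant")
wt = wild_type_genotype("WT", REFERENCE)
genotypes = {"mutant": mutant, "WT": wt}

pool = PoolSpec("pool", ("mutant",) + ("WT",) * 41)           # 1 MT : 41 WT
undiluted = simulate_pool_reads(pool, genotypes, error, coverage=20_000, seed=1)
wt_source = simulate_pool_reads(PoolSpec("w", ("WT",) * 84), genotypes, error, 20_000, seed=2)
control   = simulate_pool_reads(PoolSpec("c", ("WT",) * 84), genotypes, error, 20_000, seed=3)
diluted = dilute_reads(undiluted, wt_source, factor=6, seed=4)

baseline = estimate_baseline(control, REFERENCE)
pair = DilutionPair(compute_nvf(undiluted, REFERENCE), compute_nvf(diluted, REFERENCE))
call = dilution_contrast_call(pair, baseline, pool_id="pool")
print(call.positive, call.locus_text)
```

prints

```
True Nucleotide positions 48–59
```

the single mutant plant is detected from a 42-plant pool, and the flagged
interval 48–59 is exactly the span of the four indels the generator hid in
it (run `examples/02_sequencing_screen.py` for the per-position NVF
evidence table). Mutation descriptions use the field's phrasing:

```python
from poolscreen.mutations import describe_window_allele
describe_window_allele("AAATGATG", REFERENCE)[0].text
# '5 bp deletion @ positions 45–49'
```

The `examples/` directory has one short script per capability: allele
description, the sequencing screen, the HRM screen, the transgene assay,
and the full three-stage pipeline (`05_full_screen.py` screens an 84-shoot
cohort and recovers both hidden mutants). A thin CLI mirrors the stages:
`poolscreen simulate | screen-seq | screen-hrm | classify | run-all |
report`.

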