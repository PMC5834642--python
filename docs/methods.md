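# Methods

This note documents the models behind `poolscreen`, the defaults and why
they were chosen, the numerical conventions, and the limits of what the
synthetic data can show.

## Coordinates and the packaged reference

All positions are 1-based and inclusive. The screen's unit of analysis is a
186-bp PCR amplicon spanning the sgRNA target in the fourth exon of the
tetraploid tobacco *PDS* gene. The true genomic sequence of that amplicon is
not public; what is fixed by the published materials is its length and
primer pair, the wild-type context `AAAGATGATGATG` at positions 43–55 in
which every reported indel falls, and a `TGG` PAM 3′ of the indel cluster.
The packaged `REFERENCE` therefore consists of the forward primer
(positions 1–18), the printed context (43–55), the PAM (56–58), the reverse
complement of the reverse primer (166–186), and deterministic seeded filler
elsewhere. Construction constraints: the context occurs exactly once, there
is no homopolymer ≥ 6 bp, and position 98 is not `A` (so the one published
deletion reaching position 98 left-normalizes to its printed start). The
resulting sequence is frozen as a constant. Because the filler is synthetic,
only within-window coordinates (and the length arithmetic of long
deletions) are meaningful; that is all the published descriptions
constrain.

The NVF window is 77 bp at positions 14–90, centred on the canonical cut
site (3 bp 5′ of the PAM, between positions 52 and 53); the width is the
published analysis window, its placement within the amplicon was not
published and is configurable.

## Alignment and indel normalization

Reads and candidate alleles are aligned semiglobally: the query end-to-end
against a contiguous reference segment, terminal reference overhangs free.
Scoring: match +2, mismatch −3, and affine gaps costing `−5 − k` for length
k. These values are conventional; nothing downstream depends on them beyond
separating true indel alignments from mismatch re-interpretations (a 1-bp
gap costs two mismatches). The engine is Biopython's `PairwiseAligner`,
with a gapless fast path for equal-length pairs whenever the gapless score
provably dominates any gapped alignment (at these scores: at most one
mismatch). Ties among co-optimal alignments are resolved by the aligner's
first result; this is harmless because **every indel is left-normalized
before being reported or counted**: it is shifted to the smallest reference
coordinate among all placements producing the same mutated sequence, and
the full interval of equivalent placements is retained. Insertions are
numbered by the position the first inserted base assumes (insertion
*before* reference position p), which is what phrasings like
"insertion @ position 51 or 52" count; the test suite checks normalization
against exhaustive placement enumeration.

`describe_allele` refuses to guess: an allele needing more than 2 indels or
2 substitutions (configurable) is returned as a `complex allele` sentinel
rather than a possibly wrong simple call. Printed window-level alleles are
described by implanting them between the reference flanks
(`describe_window_allele`) — a bare 7-bp window such as `AAAGATG` is
literally a substring of the wild type and cannot be interpreted without
its flanking context.

## NVF and the dilution-contrast call

A read contributes a variant at position i if its aligned base mismatches
the reference there, if i lies inside a deletion in the read, or if the
read carries an insertion whose left-anchor base is i (one count per
insertion; whether the original analysis counted insertions at all is not
documented — deletions dominate the observed spectrum, so this convention
matters little). Reads scoring below 60% of the maximum alignment score are
excluded and tallied (`n_failed_qc`); this keeps unalignable artifacts from
inflating NVF.

The published rule — "elevated NVF, reduced on ×6 dilution" — is not
quantified, so the call is made explicit as three per-position conditions:

1. variant count > wild-type baseline by a one-sided binomial test at
   α = 0.05, Bonferroni-corrected over the 77 window positions (no
   cross-pool correction: pools are independent decisions);
2. NVF_undiluted ≥ θ = 0.005 (an absolute floor ≈ one mutant allele in a
   42-plant pool, 1/168 ≈ 0.6%);
3. NVF_diluted ≤ ρ · NVF_undiluted with ρ = 0.6. Under a true mutation the
   expected ratio is ≈ 1/7 plus the error floor (≈ 0.43 at default error
   rates); under pure error it is ≈ 1. ρ sits between them.

A pool is positive iff ≥ 1 position is flagged; the reported locus is the
min–max span of flagged positions. The scaling law
E[NVF_d] = NVF_u/(1+f) + f·baseline/(1+f) holds by construction of the
dilution model and is verified on simulations.

**Sensitivity boundary.** At 20,000× coverage a position supported by a
single mutant allele of one plant in a 42-plant pool sits ~2.8σ from the
ρ-condition boundary, so *exact* interval recovery occasionally drops such
an endpoint position; pool-level detection is unaffected (multi-allele
positions are far from all thresholds). The detailed locus-recovery test
therefore runs at 60,000×, the coverage the original experiment used;
the blind-set tests run at the 20,000× desk scale.

## Synthetic data

The generators define the study conditions; all are bit-reproducible under
fixed seeds.

* **Genotypes.** Tetraploid, tetra-allelic: each of 4 alleles carries one
  indel drawn from the empirically observed spectrum (deletions of
  1/2/4/5/6 bp and 1-bp insertions, weighted 4:7:1:2:2:5 as observed across
  the characterized lines), placed within ±5 bp of the cut site and
  left-normalized; with probability 0.05 an allele instead carries a long
  deletion (40–60 bp), mirroring the one observed 48-bp allele. T-DNA
  presence is drawn at the observed transgenic fraction (0.828), all three
  regions integrating together; partial integrations can be constructed
  explicitly.
* **Reads.** Full-amplicon reads (the original 2×150 paired-end reads span
  the 186-bp amplicon completely, so merging adds nothing; a `paired_150`
  mode is accepted and produces identical pre-merged reads). Each read
  samples one allele of one member with probability weight/4, then receives
  per-base substitution errors (default 0.003) and 1-bp indel errors
  (default 0.0005). The true instrument error background is not published;
  these defaults are a plausible amplicon floor placed well below the
  single-allele signal of 1/168, and they are what the baseline estimator
  must recover. PCR amplification bias is *not* modeled (no calibration
  exists for it). Default desk coverage is 20,000 reads per library
  (configurable to the study's 60,000–100,000×); triplicate sequencing runs
  are modeled as pooled reads, not averaged replicates.
* **Dilution.** Read-level binomial mixture: each output read comes from
  the pool with probability 1/(1+factor), else from an 84-plant wild-type
  library — equivalent to mixing PCR product mass under the no-bias
  assumption.
* **Melt curves.** Strand reannealing is random: duplex (i,j) forms with
  probability p_i·p_j. A homoduplex melts at its allele Tm (wild type
  84.0 °C; mutants shifted down 0.3 °C per indel bp, capped at 1.5 °C); a
  heteroduplex at min(Tm_i, Tm_j) − 2.0 °C. Fluorescence is the
  duplex-weighted sum of logistic transitions of width 0.6 °C on a
  65–95 °C grid at 0.2 °C steps, plus Gaussian noise (SD 0.002 RFU),
  triplicate. No thermodynamics is computed from sequence: the published
  record constrains only the relative separability of pool sizes (clear
  down to 1:19, chosen operating point 1:6), which these defaults
  reproduce; absolute Tm values are placeholders.
* **Blind sets.** The default configurations reproduce the published
  single-blind designs (eight 42-plant pools, 5 mutant + 3 WT; eight
  7-plant pools, 5 + 3) under shuffled labels with a sealed JSON manifest
  (truth, seeds, parameters, file checksums).

## HRM analysis

Curves are normalized per replicate by an affine rescale: pre-melt window
(70–75 °C) mean to 1, post-melt (90–95 °C) mean to 0 — windows are
configurable; only the 65–95 °C sweep is documented. The difference curve
is the replicate-mean normalized sample minus the wild-type reference
mean, retaining the per-temperature replicate SD. The decision statistic is
max |ΔRFU| over the grid, thresholded at k = 5 × median replicate SD. The
instrument software's actual decision rule (clustering vs threshold) is
proprietary; this statistic is the simplest one that reproduces the
published separations on the stated curve model, and k = 5 keeps the
wild-type-vs-wild-type maximum (≈ 3σ of the replicate-averaged noise over
151 grid points) comfortably below threshold. With noise set to zero the
replicate SD degenerates to 0; any nonzero deviation is then called
positive, with a warning.

1:1 confirmation mixes the candidate's four alleles (1/8 each) with wild
type (1/2): even a mutant homozygous for one indel across all four alleles
yields a heteroduplex fraction of 2·(1/2)·(1/2) = 0.5 and is cleanly
positive.

## Pipeline and reporting

Stage-1 pools are filled deterministically in plant order (default 42, last
pool possibly smaller — the smaller pool has a *higher* mutant fraction, so
the same thresholds only gain sensitivity); each positive stage-1 pool is
partitioned into stage-2 pools of 7; each plant of a positive stage-2 pool
is confirmed 1:1. Stage-1 positives with no stage-2 positive are reported
as `unresolved` rather than silently dropped, mirroring the protocol's
tolerance of stage-1 false positives (they are caught at the next stage).
Every reported mutant carries an audit trace of its three positive calls,
its per-allele mutation descriptions, and its transgene status from the
in-silico three-primer assay (strict matching: zero mismatches, exact
3′-terminal base). Efficiency percentages are recomputed from integer
counts with half-up rounding to one decimal (e.g. 100·59/88 = 67.0); zero
denominators give explicit `None`, never NaN.

## Problem sizes used by the tests

Blind sets run at the published designs (8×42 and 8×7 pools) with 20,000
reads per library; the end-to-end property screens 200-plant cohorts with
0/1/3/5 embedded mutants; the false-positive control screens 50 wild-type
42-plant pools. These sizes were chosen so the full suite exercises every
stage at realistic pool compositions while remaining a desk computation.

## Known limitations

* The reference flanks, T-DNA regions and all Tm values are synthetic
  stand-ins; conclusions about real primers, real melt temperatures or
  off-target placements cannot be drawn from them.
* The error model is i.i.d. per base — no quality- or position-dependent
  error, no PCR chimeras, no amplification bias. Passing tests show the
  decision rules behave correctly *under the stated generative model*, not
  that the thresholds are optimal for any particular instrument.
* Tetraploidy is assumed throughout (allele weight = tissue weight / 4);
  mosaic plants and partial (non-tetra-allelic) mutants are representable
  as genotypes but are not part of the default generators.
* The wet-lab quantities (regeneration rates, bench time) are inputs to the
  efficiency arithmetic, not outputs of any simulation here.
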