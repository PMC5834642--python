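"""NVF profiles, baseline estimation and the dilution-contrast pool call."""

import math
from collections import Counter

import numpy as np
import pytest

from poolscreen import (
    REFERENCE,
    CallParams,
    DilutionPair,
    ErrorModel,
    IndelCall,
    apply_mutation,
    compute_nvf,
    dilution_contrast_call,
    estimate_baseline,
    simulate_pool_reads,
    summarize_screen,
    dilute_reads,
)
from poolscreen.nvf import EmptyReadSetError, NVFProfile
from poolscreen.simulate import PoolSpec

from conftest import genotype_from_calls, PDS12_CALLS

REF = REFERENCE.sequence
WINDOW = REFERENCE.target_window


def _profile_as_dict(profile: NVFProfile) -> dict[int, tuple[int, int]]:
    return {
        int(p): (int(c), int(v))
        for p, c, v in zip(profile.positions, profile.coverage, profile.variant_count)
    }


# ---------------------------------------------------------------------------
# compute_nvf
# ---------------------------------------------------------------------------

def test_error_free_wt_reads_have_zero_nvf_everywhere():
    profile = compute_nvf([REF] * 50, REFERENCE)
    assert profile.nvf.max() == 0.0
    assert profile.coverage.min() == 50
    assert profile.n_failed_qc == 0


def test_empty_read_set_is_rejected():
    with pytest.raises(EmptyReadSetError):
        compute_nvf([], REFERENCE)


def test_profile_matches_naive_per_read_recount():
    """Small instances with known per-read edits: the profile equals a
    position-by-position recount derived directly from the generating calls."""
    calls = {
        "del51": IndelCall("deletion", 1, 51, 51),
        "del45_49": IndelCall("deletion", 5, 45, 49),
        "ins51T": IndelCall("insertion", 1, 52, 52, inserted="T"),  # leftmost 51
        "sub70": IndelCall("substitution", 1, 70, 70, inserted="A" if REF[69] != "A" else "C"),
    }
    reads: list[str] = []
    expected_variants: Counter = Counter()
    plan = [("del51", 12), ("del45_49", 9), ("ins51T", 7), ("sub70", 5)]
    from poolscreen import left_normalize

    for name, count in plan:
        call = left_normalize(calls[name], REF)
        seq = apply_mutation(REF, call)
        reads.extend([seq] * count)
        for _ in range(count):
            for pos in call.variant_positions():
                expected_variants[pos] += 1
    reads.extend([REF] * 17)  # wild-type reads

    profile = compute_nvf(reads, REFERENCE)
    got = _profile_as_dict(profile)
    for pos in range(WINDOW[0], WINDOW[1] + 1):
        coverage, variants = got[pos]
        assert coverage == 50
        assert variants == expected_variants.get(pos, 0), f"position {pos}"


def test_insertion_counts_at_left_anchor_only():
    allele = apply_mutation(REF, IndelCall("insertion", 1, 51, 51, inserted="T"))
    profile = compute_nvf([allele], REFERENCE)
    got = _profile_as_dict(profile)
    flagged = [p for p, (_, v) in got.items() if v]
    assert flagged == [50]  # base left of the leftmost insertion point


def test_garbage_reads_are_qc_tallied_not_counted():
    garbage = "ACGT" * 40  # unalignable 160-mer
    profile = compute_nvf([REF] * 10 + [garbage] * 3, REFERENCE)
    assert profile.n_failed_qc == 3
    assert profile.coverage.max() == 10
    assert profile.nvf.max() == 0.0


def test_simulated_pds12_pool_elevates_only_the_verified_interval(
    pds12_genotype, wt_genotype
):
    """A 1MT:41WT pool elevates NVF across positions 45-51 and nowhere else."""
    genotypes = {"pds-12": pds12_genotype, "WT": wt_genotype}
    reads = simulate_pool_reads(
        PoolSpec("p", ("pds-12",) + ("WT",) * 41),
        genotypes,
        ErrorModel(substitution_rate=0.0, indel_error_rate=0.0),
        coverage=20_000,
        seed=13,
    )
    profile = compute_nvf(reads, REFERENCE)
    got = _profile_as_dict(profile)
    elevated = sorted(p for p, (_, v) in got.items() if v > 0)
    assert elevated == list(range(45, 52))


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------

def test_zero_error_baseline_is_zero(wt_genotype):
    reads = simulate_pool_reads(
        PoolSpec("w", ("WT",) * 10),
        {"WT": wt_genotype},
        ErrorModel(substitution_rate=0.0, indel_error_rate=0.0),
        coverage=2_000,
        seed=2,
    )
    baseline = estimate_baseline(reads, REFERENCE)
    assert baseline.nvf.max() == 0.0


def test_baseline_recovers_configured_substitution_rate(wt_genotype):
    rate = 0.003
    reads = simulate_pool_reads(
        PoolSpec("w", ("WT",) * 84),
        {"WT": wt_genotype},
        ErrorModel(substitution_rate=rate, indel_error_rate=0.0),
        coverage=40_000,
        seed=3,
    )
    baseline = estimate_baseline(reads, REFERENCE)
    mean_nvf = baseline.nvf.mean()
    n_total = baseline.profile.coverage.sum()
    sd = math.sqrt(rate * (1 - rate) / n_total)
    assert abs(mean_nvf - rate) <= 3 * sd


def test_low_coverage_baseline_warns(wt_genotype):
    reads = simulate_pool_reads(
        PoolSpec("w", ("WT",) * 5), {"WT": wt_genotype}, coverage=200, seed=4
    )
    with pytest.warns(UserWarning, match="coverage"):
        baseline = estimate_baseline(reads, REFERENCE)
    assert baseline.low_coverage


# ---------------------------------------------------------------------------
# dilution contrast
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def wt_libraries(wt_genotype):
    """Shared wild-type dilution source and baseline control (20,000x)."""
    genotypes = {"WT": wt_genotype}
    wt_src = simulate_pool_reads(
        PoolSpec("w", ("WT",) * 84), genotypes, ErrorModel(), 20_000, seed=101
    )
    wt_ctl = simulate_pool_reads(
        PoolSpec("c", ("WT",) * 84), genotypes, ErrorModel(), 20_000, seed=102
    )
    return wt_src, estimate_baseline(wt_ctl, REFERENCE)


def _screen_pool(members, genotypes, wt_libraries, seed, coverage=20_000):
    wt_src, baseline = wt_libraries
    rng = np.random.default_rng(seed)
    pool = simulate_pool_reads(
        PoolSpec("p", members), genotypes, ErrorModel(), coverage,
        seed=int(rng.integers(2**31 - 1)),
    )
    diluted = dilute_reads(pool, wt_src, 6, seed=int(rng.integers(2**31 - 1)))
    pair = DilutionPair(compute_nvf(pool, REFERENCE), compute_nvf(diluted, REFERENCE))
    return pair, baseline


def test_no_reduction_on_dilution_means_negative():
    """If the 'diluted' profile is identical to the undiluted one, the
    reduction condition fails at every position."""
    allele = apply_mutation(REF, IndelCall("deletion", 2, 49, 50))
    reads = [allele] * 40 + [REF] * 1960
    profile = compute_nvf(reads, REFERENCE)
    baseline = estimate_baseline([REF] * 2000, REFERENCE)
    call = dilution_contrast_call(DilutionPair(profile, profile), baseline)
    assert not call.positive
    assert call.flagged_positions == ()


def test_mutant_pool_flags_the_verified_locus(pds12_genotype, wt_genotype, wt_libraries):
    """Exact recovery of the 45-51 locus from a 1MT:41WT pool, at the
    deep coverage the detailed single-pool experiment used (~x60,000):
    positions supported by a single allele sit near the detection floor
    and need the full study coverage to flag reliably."""
    genotypes = {"pds-12": pds12_genotype, "WT": wt_genotype}
    pair, baseline = _screen_pool(
        ("pds-12",) + ("WT",) * 41, genotypes, wt_libraries, seed=17,
        coverage=60_000,
    )
    call = dilution_contrast_call(pair, baseline, pool_id="pds-12 pool")
    assert call.positive
    assert call.locus_interval == (45, 51)
    assert call.locus_text == "Nucleotide positions 45–51"


def test_wt_pool_is_negative(wt_genotype, wt_libraries):
    genotypes = {"WT": wt_genotype}
    pair, baseline = _screen_pool(("WT",) * 42, genotypes, wt_libraries, seed=18)
    call = dilution_contrast_call(pair, baseline)
    assert not call.positive


def test_dilution_scaling_law(pds12_genotype, wt_genotype, wt_libraries):
    """E[nvf_d] = nvf_u/(1+f) + f*baseline/(1+f) at mutated positions,
    verified within 3 binomial SDs of the locus mean (conservatively treating
    positions as fully correlated, since one deletion read spans several)."""
    genotypes = {"pds-12": pds12_genotype, "WT": wt_genotype}
    truth = pds12_genotype.truth_variant_positions(WINDOW)
    for size, seed in ((21, 31), (42, 32), (84, 33)):
        pair, baseline = _screen_pool(
            ("pds-12",) + ("WT",) * (size - 1), genotypes, wt_libraries, seed=seed
        )
        idx = np.isin(pair.undiluted.positions, truth)
        f = pair.factor
        predicted = (pair.undiluted.nvf[idx] + f * baseline.nvf[idx]) / (1 + f)
        observed = pair.diluted.nvf[idx]
        n = pair.diluted.coverage[idx]
        sd_bound = np.sqrt(predicted * (1 - predicted) / n).mean()
        assert abs(observed.mean() - predicted.mean()) <= 3 * sd_bound


def test_summarize_screen_reports_accuracy(pds12_genotype, wt_genotype, wt_libraries):
    genotypes = {"pds-12": pds12_genotype, "WT": wt_genotype}
    pair_m, baseline = _screen_pool(("pds-12",) + ("WT",) * 41, genotypes, wt_libraries, seed=41)
    call_m = dilution_contrast_call(pair_m, baseline, pool_id="A")
    pair_w, _ = _screen_pool(("WT",) * 42, genotypes, wt_libraries, seed=42)
    call_w = dilution_contrast_call(pair_w, baseline, pool_id="B")
    table = summarize_screen([call_m, call_w], truth={"A": True, "B": False})
    assert table["correct"].all()
    assert list(table["locus"])[1] == "None detected"
    assert summarize_screen([]).empty


def test_detection_is_monotone_in_pool_size(pds12_genotype, wt_genotype, wt_libraries):
    """At fixed coverage, detection does not improve as the pool grows
    (the mutant allele fraction falls from 1/21 to 1/84)."""
    genotypes = {"pds-12": pds12_genotype, "WT": wt_genotype}
    detections = []
    for size in (21, 42, 84):
        hits = 0
        for seed in (61, 62):
            pair, baseline = _screen_pool(
                ("pds-12",) + ("WT",) * (size - 1), genotypes, wt_libraries,
                seed=seed * 1000 + size,
            )
            hits += dilution_contrast_call(pair, baseline).positive
        detections.append(hits)
    assert detections == sorted(detections, reverse=True)
    assert detections[0] == 2  # the smallest pool is always detected
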