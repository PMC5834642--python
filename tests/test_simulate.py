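"""Synthetic-data generators: determinism, mixture accounting, blind sets."""

import math
from collections import Counter

import numpy as np
import pytest

from poolscreen import (
    REFERENCE,
    ErrorModel,
    HRMParams,
    allele_species,
    dilute_reads,
    duplex_species,
    generate_blind_set,
    simulate_melt_curves,
    simulate_mutant_genotype,
    simulate_pool_reads,
    write_blind_set,
)
from poolscreen.simulate import PoolSpec, ReadSet, UnknownMemberError

from conftest import PDS12_CALLS, genotype_from_calls


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def test_mutant_genotype_has_no_wild_type_allele():
    for seed in range(20):
        g = simulate_mutant_genotype(seed=seed)
        assert g.is_tetra_allelic_mutant
        assert all(a != REFERENCE.sequence for a in g.alleles)


def test_genotype_generation_is_deterministic():
    assert simulate_mutant_genotype(seed=7) == simulate_mutant_genotype(seed=7)


def test_indel_spectrum_coverage():
    """Over many draws the generator produces at least four distinct classes."""
    classes = set()
    rng = np.random.default_rng(0)
    for _ in range(250):  # 1000 alleles
        g = simulate_mutant_genotype(seed=rng)
        for calls in g.allele_calls:
            for c in calls:
                classes.add((c.kind, min(c.length, 40)))
    assert len(classes) >= 4
    kinds = {k for k, _ in classes}
    assert kinds == {"deletion", "insertion"}


def test_drawn_indels_cluster_near_cut_site():
    rng = np.random.default_rng(3)
    for _ in range(50):
        g = simulate_mutant_genotype(seed=rng)
        for calls in g.allele_calls:
            for c in calls:
                lo, hi = REFERENCE.target_window
                assert lo <= c.start <= hi


# ---------------------------------------------------------------------------
# pooled reads
# ---------------------------------------------------------------------------

def test_error_free_wt_pool_reads_equal_the_reference(wt_genotype):
    pool = PoolSpec("p", ("WT",) * 10)
    reads = simulate_pool_reads(
        pool,
        {"WT": wt_genotype},
        ErrorModel(substitution_rate=0.0, indel_error_rate=0.0),
        coverage=500,
        seed=0,
    )
    assert set(reads.counts) == {REFERENCE.sequence}
    assert reads.n_reads == 500


def test_mutant_read_fraction_matches_pool_composition(pds12_genotype, wt_genotype):
    """1 mutant among 42 plants: expected mutant-read fraction 1/42."""
    genotypes = {"pds-12": pds12_genotype, "WT": wt_genotype}
    pool = PoolSpec("p", ("pds-12",) + ("WT",) * 41)
    n = 20_000
    reads = simulate_pool_reads(pool, genotypes, ErrorModel(), coverage=n, seed=5)
    mutant_reads = sum(
        count for (plant, _), count in reads.provenance.items() if plant == "pds-12"
    )
    p = 1.0 / 42.0
    sd = math.sqrt(n * p * (1 - p))
    assert abs(mutant_reads - n * p) <= 3 * sd
    assert reads.n_reads == n


def test_unknown_pool_member_is_rejected(wt_genotype):
    pool = PoolSpec("p", ("ghost", "WT"))
    with pytest.raises(UnknownMemberError):
        simulate_pool_reads(pool, {"WT": wt_genotype}, coverage=200, seed=0)


def test_read_generation_is_deterministic(pds12_genotype, wt_genotype):
    genotypes = {"pds-12": pds12_genotype, "WT": wt_genotype}
    pool = PoolSpec("p", ("pds-12",) + ("WT",) * 6)
    a = simulate_pool_reads(pool, genotypes, coverage=2_000, seed=99)
    b = simulate_pool_reads(pool, genotypes, coverage=2_000, seed=99)
    assert a.counts == b.counts and a.provenance == b.provenance


def test_fastq_round_trip(tmp_path, wt_genotype):
    pool = PoolSpec("p", ("WT",) * 3)
    reads = simulate_pool_reads(pool, {"WT": wt_genotype}, coverage=300, seed=1)
    path = tmp_path / "pool.fastq"
    reads.to_fastq(path)
    back = ReadSet.from_fastq(path)
    assert back.counts == reads.counts


# ---------------------------------------------------------------------------
# dilution
# ---------------------------------------------------------------------------

def test_dilution_factor_zero_resamples_the_pool(pds12_genotype, wt_genotype):
    genotypes = {"pds-12": pds12_genotype, "WT": wt_genotype}
    pool = simulate_pool_reads(
        PoolSpec("p", ("pds-12", "WT")), genotypes, coverage=1_000, seed=2
    )
    wt = simulate_pool_reads(PoolSpec("w", ("WT",)), genotypes, coverage=1_000, seed=3)
    diluted = dilute_reads(pool, wt, factor=0, seed=4)
    assert diluted.n_reads == pool.n_reads
    assert set(diluted.counts) <= set(pool.counts)


def test_dilution_reduces_mutant_fraction_sevenfold(pds12_genotype, wt_genotype):
    genotypes = {"pds-12": pds12_genotype, "WT": wt_genotype}
    n = 30_000
    pool = simulate_pool_reads(
        PoolSpec("p", ("pds-12",) + ("WT",) * 41),
        genotypes,
        ErrorModel(substitution_rate=0.0, indel_error_rate=0.0),
        coverage=n,
        seed=6,
    )
    wt = simulate_pool_reads(
        PoolSpec("w", ("WT",) * 84),
        genotypes,
        ErrorModel(substitution_rate=0.0, indel_error_rate=0.0),
        coverage=n,
        seed=7,
    )
    diluted = dilute_reads(pool, wt, factor=6, seed=8)
    mutant_seqs = set(pds12_genotype.alleles)
    observed = sum(c for s, c in diluted.counts.items() if s in mutant_seqs)
    p = (1.0 / 42.0) / 7.0
    sd = math.sqrt(n * p * (1 - p))
    assert abs(observed - n * p) <= 3 * sd


def test_negative_dilution_factor_rejected(wt_genotype):
    reads = simulate_pool_reads(
        PoolSpec("p", ("WT",)), {"WT": wt_genotype}, coverage=200, seed=0
    )
    with pytest.raises(ValueError):
        dilute_reads(reads, reads, factor=-1, seed=0)


# ---------------------------------------------------------------------------
# melt curves
# ---------------------------------------------------------------------------

def test_duplex_weights_sum_to_one(pds12_genotype, wt_genotype):
    species = allele_species([pds12_genotype] + [wt_genotype] * 6)
    duplexes = duplex_species(species)
    assert sum(w for w, _ in duplexes) == pytest.approx(1.0)


def test_heteroduplex_fraction_by_direct_enumeration(wt_genotype):
    """A 1:1 mutant:WT mix with four distinct mutant alleles: heteroduplex
    fraction equals 1 - sum(p_i^2) from direct strand-pair enumeration."""
    mutant = genotype_from_calls("m", PDS12_CALLS)
    params = HRMParams()
    species = allele_species([mutant, wt_genotype], params=params)
    duplexes = duplex_species(species, params)
    het = sum(
        w
        for (w, tm), (i, j) in zip(
            duplexes,
            [(i, j) for i in range(len(species)) for j in range(len(species)) if j >= i],
        )
        if i != j
    )
    # fractions: WT 1/2, four distinct mutant alleles 1/8 each
    expected = 1.0 - (0.5**2 + 4 * 0.125**2)
    assert het == pytest.approx(expected)


def test_wt_only_pool_replicates_differ_only_by_noise(wt_genotype):
    params = HRMParams(noise_sd=0.002)
    curves = simulate_melt_curves(
        allele_species([wt_genotype] * 7, params=params), params, seed=3
    )
    spread = np.ptp(curves.rfu, axis=0)
    assert spread.max() < 6 * params.noise_sd


def test_melt_curves_deterministic_under_seed(wt_genotype):
    params = HRMParams()
    species = allele_species([wt_genotype] * 2, params=params)
    a = simulate_melt_curves(species, params, seed=11)
    b = simulate_melt_curves(species, params, seed=11)
    assert np.array_equal(a.rfu, b.rfu)


def test_fractions_must_sum_to_one():
    from poolscreen.simulate import AlleleSpecies

    with pytest.raises(ValueError):
        duplex_species([AlleleSpecies("A" * 10, 0.6, 84.0)])


# ---------------------------------------------------------------------------
# blind sets
# ---------------------------------------------------------------------------

def test_default_seq_blind_set_is_five_plus_three():
    blind = generate_blind_set(stage="seq42", coverage=300, seed=5)
    assert len(blind.pools) == 8
    truth = [v["mutant"] for v in blind.manifest.pools.values()]
    assert sum(truth) == 5
    for label, (undiluted, diluted) in blind.pools.items():
        assert undiluted.n_reads == 300
        assert diluted.n_reads == 300


def test_default_hrm_blind_set_is_five_plus_three():
    blind = generate_blind_set(stage="hrm7", seed=5)
    assert len(blind.pools) == 8
    assert sum(v["mutant"] for v in blind.manifest.pools.values()) == 5
    assert blind.manifest.params["pool_size"] == 7


def test_blind_labels_shuffle_deterministically():
    def flags_by_label(blind):
        return [blind.manifest.pools[k]["mutant"] for k in sorted(blind.manifest.pools)]

    a = generate_blind_set(stage="hrm7", seed=21)
    b = generate_blind_set(stage="hrm7", seed=21)
    assert a.manifest.pools == b.manifest.pools
    # and the label assignment is genuinely shuffled, not slot order
    assert flags_by_label(a) != [True] * 5 + [False] * 3 or flags_by_label(
        generate_blind_set(stage="hrm7", seed=22)
    ) != flags_by_label(a)


def test_written_blind_set_lists_every_file_with_checksum(tmp_path):
    import hashlib
    import json

    blind = generate_blind_set(stage="seq42", n_mutant_pools=1, n_wt_pools=1,
                               pool_size=4, coverage=150, seed=9)
    manifest_path = write_blind_set(blind, tmp_path)
    manifest = json.loads(manifest_path.read_text())
    files = manifest["files"]
    emitted = {p.name for p in tmp_path.iterdir()} - {"manifest.json"}
    assert set(files) == emitted
    for name, digest in files.items():
        assert hashlib.sha256((tmp_path / name).read_bytes()).hexdigest() == digest
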