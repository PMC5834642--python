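"""Synthetic data generators for every input the screen consumes.

The generators emulate the study conditions end to end: tetraploid plants in
which all four target-gene alleles carry an indel drawn from the observed
mutation spectrum; leaf-tissue pools of 1 mutant : N-1 wild-type plants;
pooled amplicon libraries at deep coverage with substitution/indel
sequencing error; the 1:6 dilution of a pool's PCR product with wild-type
product; triplicate melt curves with homo-/heteroduplex structure; and
single-blind pool sets with sealed ground-truth manifests.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import expit

from .hrm import MeltCurveSet
from .mutations import IndelCall, apply_mutation, left_normalize
from .plants import PlantGenotype, TDNAStatus, wild_type_genotype
from .reference import CUT_SITE, REFERENCE, ReferenceAmplicon

__all__ = [
    "ErrorModel",
    "PoolSpec",
    "ReadSet",
    "HRMParams",
    "AlleleSpecies",
    "Manifest",
    "BlindSet",
    "simulate_mutant_genotype",
    "simulate_pool_reads",
    "dilute_reads",
    "allele_species",
    "duplex_species",
    "simulate_melt_curves",
    "generate_blind_set",
    "write_blind_set",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CONSTANT_QUALITY = 37  # Phred score written for every simulated base


class UnknownMemberError(KeyError):
    """Raised when a pool references a plant without a genotype."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorModel:
    """Per-base sequencing error model.

    The real error background of the instrument is not published; the
    defaults are chosen as a plausible amplicon-sequencing floor such that
    error-driven variant frequencies sit well below a single mutant allele
    diluted 1:167 (one allele of one plant among 42).
    """

    substitution_rate: float = 0.003
    indel_error_rate: float = 0.0005
    read_length_mode: str = "full_amplicon"

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "indel_error_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 0.05:
                raise ValueError(f"{name} must be in [0, 0.05], got {rate}")
        if self.read_length_mode not in ("full_amplicon", "paired_150"):
            raise ValueError(f"unknown read_length_mode {self.read_length_mode!r}")


@dataclass(frozen=True)
class PoolSpec:
    """Which plants are pooled, with per-plant tissue weights summing to 1."""

    pool_id: str
    members: tuple[str, ...]
    weights: tuple[float, ...] = ()
    stage: str = "seq42"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a pool needs at least one member")
        weights = self.weights or tuple(1.0 / len(self.members) for _ in self.members)
        if len(weights) != len(self.members):
            raise ValueError("one weight per member required")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("member weights must sum to 1")
        object.__setattr__(self, "weights", weights)
        if self.stage not in ("seq42", "hrm7", "hrm1to1"):
            raise ValueError(f"unknown stage {self.stage!r}")
        limit = 84 if self.stage == "seq42" else 30
        if len(self.members) > limit:
            raise ValueError(
                f"stage {self.stage} pools are limited to {limit} members"
            )


@dataclass(frozen=True)
class HRMParams:
    """Melt-curve model parameters.

    The wild-type homoduplex melts at ``tm_wt``; a mutant homoduplex is
    shifted down by ``homo_mut_tm_shift`` degrees per indel bp (capped at
    ``homo_mut_tm_cap``), and a heteroduplex melts ``het_tm_shift`` degrees
    below the lower-melting of its two strands.  Fluorescence follows a
    logistic melt transition of width ``transition_width`` per duplex
    species, plus Gaussian noise.
    """

    tm_wt: float = 84.0
    het_tm_shift: float = 2.0
    homo_mut_tm_shift: float = 0.3
    homo_mut_tm_cap: float = 1.5
    transition_width: float = 0.6
    temp_min: float = 65.0
    temp_max: float = 95.0
    temp_step: float = 0.2
    noise_sd: float = 0.002
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.temp_step <= 0 or self.temp_max <= self.temp_min:
            raise ValueError("temperature grid must be increasing")
        if self.replicates < 1:
            raise ValueError("at least one replicate required")

    @property
    def temperatures(self) -> np.ndarray:
        n = int(round((self.temp_max - self.temp_min) / self.temp_step)) + 1
        return np.round(self.temp_min + self.temp_step * np.arange(n), 6)


# ---------------------------------------------------------------------------
# read sets
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """A pool's simulated reads, stored as sequence -> multiplicity counts.

    ``provenance`` is a truth side channel (never written to FASTQ): counts
    per ``(plant_id, allele_index)`` source, or per mixture component for
    diluted sets.
    """

    counts: Counter
    ref_id: str = REFERENCE.id
    provenance: Counter = field(default_factory=Counter)

    @property
    def n_reads(self) -> int:
        return int(sum(self.counts.values()))

    def sequences(self) -> Iterable[tuple[str, int]]:
        return self.counts.items()

    def to_fastq(self, path) -> None:
        """Write plain four-line FASTQ (constant Phred+33 quality, headers
        carry no truth information)."""
        qual_char = chr(_CONSTANT_QUALITY + 33)
        with open(path, "w") as fh:
            i = 0
            for seq, count in sorted(self.counts.items()):
                for _ in range(count):
                    i += 1
                    fh.write(f"@read_{i:07d}\n{seq}\n+\n{qual_char * len(seq)}\n")

    @classmethod
    def from_fastq(cls, path, ref_id: str = REFERENCE.id) -> "ReadSet":
        from Bio import SeqIO

        counts: Counter = Counter()
        for record in SeqIO.parse(str(path), "fastq"):
            counts[str(record.seq).upper()] += 1
        return cls(counts=counts, ref_id=ref_id)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

# Empirical indel spectrum of the characterized mutant lines: (kind, length)
# weighted by how often each class was observed across alleles.
TABLE_SPECTRUM: tuple[tuple[str, int, int], ...] = (
    ("deletion", 1, 4),
    ("deletion", 2, 7),
    ("deletion", 4, 1),
    ("deletion", 5, 2),
    ("deletion", 6, 2),
    ("insertion", 1, 5),
)

#: Probability that an allele carries a rare long deletion (>= 40 bp).
LONG_DELETION_PROB = 0.05
LONG_DELETION_RANGE = (40, 60)


def _draw_indel(rng: np.random.Generator, ref: ReferenceAmplicon) -> IndelCall:
    """One allele's edit: class from the empirical spectrum, placed so the
    edited bases fall within +/-5 bp of the cut site."""
    L = ref.length
    if rng.random() < LONG_DELETION_PROB:
        length = int(rng.integers(LONG_DELETION_RANGE[0], LONG_DELETION_RANGE[1] + 1))
        start = int(rng.integers(CUT_SITE - 5, CUT_SITE + 3))
        end = min(start + length - 1, L - 1)
        call = IndelCall("deletion", end - start + 1, start, end)
    else:
        kinds = [(k, l) for k, l, w in TABLE_SPECTRUM]
        weights = np.array([w for _, _, w in TABLE_SPECTRUM], dtype=float)
        kind, length = kinds[int(rng.choice(len(kinds), p=weights / weights.sum()))]
        if kind == "deletion":
            pivot = int(rng.integers(CUT_SITE - 5, CUT_SITE + 6))
            start = int(rng.integers(pivot - length + 1, pivot + 1))
            start = max(2, min(start, L - length))
            call = IndelCall("deletion", length, start, start + length - 1)
        else:
            pos = int(rng.integers(CUT_SITE - 5, CUT_SITE + 6))
            base = "ACGT"[int(rng.integers(4))]
            call = IndelCall("insertion", 1, pos, pos, inserted=base)
    return left_normalize(call, ref.sequence)


def simulate_mutant_genotype(
    ref: ReferenceAmplicon = REFERENCE,
    seed: int | np.random.Generator = 0,
    plant_id: str = "mutant",
    transgenic: bool | None = None,
    transgenic_prob: float = 0.828,
) -> PlantGenotype:
    """A tetra-allelic mutant: four alleles, each carrying one drawn indel.

    Alleles need not be distinct but none is wild type.  T-DNA presence is
    drawn with probability ``transgenic_prob`` (all three regions integrate
    together) unless ``transgenic`` is forced.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alleles = []
    calls = []
    for _ in range(4):
        call = _draw_indel(rng, ref)
        alleles.append(apply_mutation(ref.sequence, call))
        calls.append((call,))
    if transgenic is None:
        transgenic = bool(rng.random() < transgenic_prob)
    tdna = (
        TDNAStatus(border_35s=True, cas9=True, kanr=True)
        if transgenic
        else TDNAStatus()
    )
    return PlantGenotype(
        plant_id=plant_id,
        alleles=tuple(alleles),
        allele_calls=tuple(calls),
        tdna=tdna,
    )


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _mutate_allele_reads(
    allele: str, n: int, error: ErrorModel, rng: np.random.Generator, counts: Counter
) -> None:
    """Add ``n`` reads of ``allele`` to ``counts`` with per-base errors."""
    if n == 0:
        return
    L = len(allele)
    n_sub = rng.binomial(L, error.substitution_rate, size=n)
    n_ind = rng.binomial(L, error.indel_error_rate, size=n)
    clean = (n_sub == 0) & (n_ind == 0)
    n_clean = int(clean.sum())
    if n_clean:
        counts[allele] += n_clean

    arr = np.frombuffer(allele.encode(), dtype=np.uint8)
    sub_only = np.nonzero(~clean & (n_ind == 0))[0]
    if sub_only.size:
        mat = np.repeat(arr[None, :], sub_only.size, axis=0)
        for row, idx in enumerate(sub_only):
            k = int(n_sub[idx])
            pos = rng.choice(L, size=k, replace=False)
            # substitute with a uniformly chosen different base
            orig = mat[row, pos]
            offs = rng.integers(1, 4, size=k)
            idx_in_bases = np.searchsorted(_BASES, orig)
            mat[row, pos] = _BASES[(idx_in_bases + offs) % 4]
        for row in range(mat.shape[0]):
            counts[mat[row].tobytes().decode()] += 1

    with_indel = np.nonzero(n_ind > 0)[0]
    for idx in with_indel:
        seq = list(allele)
        k_sub = int(n_sub[idx])
        for p in rng.choice(L, size=k_sub, replace=False):
            current = seq[p]
            choices = [b for b in "ACGT" if b != current]
            seq[p] = choices[int(rng.integers(3))]
        for _ in range(int(n_ind[idx])):
            p = int(rng.integers(len(seq)))
            if rng.random() < 0.5 and len(seq) > 1:
                del seq[p]
            else:
                seq.insert(p, "ACGT"[int(rng.integers(4))])
        counts["".join(seq)] += 1


def simulate_pool_reads(
    pool: PoolSpec,
    genotypes: Mapping[str, PlantGenotype],
    error: ErrorModel = ErrorModel(),
    coverage: int = 20_000,
    seed: int = 0,
) -> ReadSet:
    """Simulate a pooled amplicon library.

    Each read is drawn from one allele of one member, with probability
    ``weight / 4`` per allele; sequencing errors are injected per the error
    model.  With full-amplicon reads, ``coverage`` equals the read count.
    In ``paired_150`` mode, 2x150 bp pairs fully span the 186-bp amplicon
    and are emitted pre-merged, so the read content is identical.
    """
    if coverage < 100:
        raise ValueError("coverage must be >= 100")
    rng = np.random.default_rng(seed)
    sources: list[tuple[str, int, str]] = []  # (plant_id, allele_idx, sequence)
    probs: list[float] = []
    for plant_id, weight in zip(pool.members, pool.weights):
        if plant_id not in genotypes:
            raise UnknownMemberError(f"no genotype for pool member {plant_id!r}")
        g = genotypes[plant_id]
        for a_idx, allele in enumerate(g.alleles):
            sources.append((plant_id, a_idx, allele))
            probs.append(weight / 4.0)
    draw = rng.multinomial(coverage, np.asarray(probs))
    counts: Counter = Counter()
    provenance: Counter = Counter()
    for (plant_id, a_idx, allele), n in zip(sources, draw):
        if n:
            provenance[(plant_id, a_idx)] += int(n)
            _mutate_allele_reads(allele, int(n), error, rng, counts)
    return ReadSet(counts=counts, provenance=provenance)


def dilute_reads(
    pool_reads: ReadSet,
    wt_reads: ReadSet,
    factor: float = 6.0,
    seed: int = 0,
) -> ReadSet:
    """Mix a pool library with wild-type product at 1 : ``factor``.

    Each output read is drawn from the pool with probability
    ``1 / (1 + factor)`` and from the wild-type library otherwise; output
    size matches the pool library.  Models mixing PCR product mass under
    equal amplification.
    """
    if factor < 0:
        raise ValueError("dilution factor must be >= 0")
    if pool_reads.ref_id != wt_reads.ref_id:
        raise ValueError("read sets come from different references")
    rng = np.random.default_rng(seed)
    n = pool_reads.n_reads
    n_pool = int(rng.binomial(n, 1.0 / (1.0 + factor)))
    counts: Counter = Counter()
    for source, k in ((pool_reads, n_pool), (wt_reads, n - n_pool)):
        if k == 0:
            continue
        seqs = list(source.counts.keys())
        weights = np.fromiter(source.counts.values(), dtype=float)
        draw = rng.multinomial(k, weights / weights.sum())
        for seq, m in zip(seqs, draw):
            if m:
                counts[seq] += int(m)
    return ReadSet(
        counts=counts,
        ref_id=pool_reads.ref_id,
        provenance=Counter({("pool",): n_pool, ("wt",): n - n_pool}),
    )


# ---------------------------------------------------------------------------
# melt curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleSpecies:
    """A distinct allele sequence in a pool with its fraction and strand Tm."""

    key: str
    fraction: float
    tm: float


def allele_species(
    genotypes: Sequence[PlantGenotype],
    weights: Sequence[float] | None = None,
    params: HRMParams | None = None,
) -> list[AlleleSpecies]:
    """Collapse pooled genotypes into distinct allele species.

    Mutant strand Tm is shifted below the wild-type Tm in proportion to the
    allele's total indel length (capped).
    """
    if params is None:
        params = HRMParams()
    if weights is None:
        weights = [1.0 / len(genotypes)] * len(genotypes)
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("genotype weights must sum to 1")
    fractions: dict[str, float] = {}
    tms: dict[str, float] = {}
    for g, w in zip(genotypes, weights):
        for allele, calls in zip(g.alleles, g.allele_calls):
            indel_bp = sum(c.length for c in calls if c.kind != "substitution")
            tm = params.tm_wt - min(
                params.homo_mut_tm_shift * indel_bp, params.homo_mut_tm_cap
            )
            fractions[allele] = fractions.get(allele, 0.0) + w / 4.0
            tms[allele] = tm
    return [
        AlleleSpecies(key=seq, fraction=frac, tm=tms[seq])
        for seq, frac in fractions.items()
    ]


def duplex_species(
    species: Sequence[AlleleSpecies], params: HRMParams | None = None
) -> list[tuple[float, float]]:
    """Duplex (weight, Tm) pairs under random strand reannealing.

    Strand pair (i, j) forms with probability ``p_i * p_j``; a homoduplex
    melts at its own Tm, a heteroduplex at ``min(Tm_i, Tm_j) -
    het_tm_shift``.  Weights sum to 1.
    """
    if params is None:
        params = HRMParams()
    total = sum(s.fraction for s in species)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"allele fractions must sum to 1 (got {total})")
    out: list[tuple[float, float]] = []
    for i, a in enumerate(species):
        for j, b in enumerate(species):
            if j < i:
                continue
            if i == j:
                out.append((a.fraction * b.fraction, a.tm))
            else:
                out.append(
                    (2.0 * a.fraction * b.fraction, min(a.tm, b.tm) - params.het_tm_shift)
                )
    return out


def simulate_melt_curves(
    composition: Sequence[AlleleSpecies],
    params: HRMParams | None = None,
    seed: int = 0,
    sample_id: str = "sample",
    replicates: int | None = None,
) -> MeltCurveSet:
    """Triplicate (by default) fluorescence traces for a pool composition.

    Fluorescence at temperature T is the duplex-weighted sum of logistic
    melt transitions plus independent Gaussian noise per replicate."""
    if params is None:
        params = HRMParams()
    reps = params.replicates if replicates is None else replicates
    rng = np.random.default_rng(seed)
    temps = params.temperatures
    duplexes = duplex_species(composition, params)
    signal = np.zeros_like(temps)
    for weight, tm in duplexes:
        signal = signal + weight * expit((tm - temps) / params.transition_width)
    rfu = signal[None, :] + rng.normal(0.0, params.noise_sd, size=(reps, temps.size))
    return MeltCurveSet(sample_id=sample_id, temperatures=temps, rfu=rfu)


# ---------------------------------------------------------------------------
# blind sets
# ---------------------------------------------------------------------------

@dataclass
class Manifest:
    """Sealed ground truth for a blind set: per-pool truth, seeds, files."""

    stage: str
    seed: int
    pools: dict[str, dict]
    params: dict
    files: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "stage": self.stage,
                "seed": self.seed,
                "pools": self.pools,
                "params": self.params,
                "files": self.files,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "Manifest":
        d = json.loads(text)
        return cls(
            stage=d["stage"],
            seed=d["seed"],
            pools=d["pools"],
            params=d["params"],
            files=d.get("files", {}),
        )


@dataclass
class BlindSet:
    """Randomly labelled pools plus their sealed manifest.

    For the sequencing stage each pool carries ``(undiluted, diluted)``
    read sets and a shared wild-type control library; for the HRM stage
    each pool carries a :class:`MeltCurveSet` and the control is a
    wild-type curve set.
    """

    stage: str
    pools: dict[str, object]
    wt_control: object
    manifest: Manifest
    genotypes: dict[str, PlantGenotype] = field(default_factory=dict)


def _pool_truth(label: str, genotype: PlantGenotype | None, window) -> dict:
    if genotype is None:
        return {"mutant": False, "plant_id": None, "calls": [], "truth_positions": []}
    calls = [
        json.loads(c.to_json()) for calls in genotype.allele_calls for c in calls
    ]
    return {
        "mutant": True,
        "plant_id": genotype.plant_id,
        "calls": calls,
        "truth_positions": list(genotype.truth_variant_positions(window)),
    }


def generate_blind_set(
    stage: str = "seq42",
    n_mutant_pools: int = 5,
    n_wt_pools: int = 3,
    pool_size: int | None = None,
    ref: ReferenceAmplicon = REFERENCE,
    coverage: int = 20_000,
    error: ErrorModel | None = None,
    hrm_params: HRMParams | None = None,
    dilution_factor: float = 6.0,
    wt_pool_size: int = 84,
    seed: int = 0,
) -> BlindSet:
    """Build a single-blind pool set with a sealed truth manifest.

    The default configuration reproduces the published blind designs: eight
    42-plant pools (five containing one tetra-allelic mutant each, three
    wild-type-only) for the sequencing stage, and eight 7-plant pools (5+3)
    for the HRM stage.  Pool labels are shuffled deterministically under the
    seed; the manifest maps labels back to truth.
    """
    if n_mutant_pools < 0 or n_wt_pools < 0:
        raise ValueError("pool counts must be >= 0")
    if stage not in ("seq42", "hrm7"):
        raise ValueError(f"unknown blind-set stage {stage!r}")
    if pool_size is None:
        pool_size = 42 if stage == "seq42" else 7
    error = error or ErrorModel()
    hrm_params = hrm_params or HRMParams()
    rng = np.random.default_rng(seed)
    n_pools = n_mutant_pools + n_wt_pools
    labels = [f"pool_{i + 1:02d}" for i in range(n_pools)]
    order = rng.permutation(n_pools)  # order[k] = pool slot for label k

    genotypes: dict[str, PlantGenotype] = {"WT": wild_type_genotype("WT", ref)}
    mutants = [
        simulate_mutant_genotype(
            ref, seed=rng, plant_id=f"mutant_{i + 1:02d}"
        )
        for i in range(n_mutant_pools)
    ]
    for m in mutants:
        genotypes[m.plant_id] = m

    pools: dict[str, object] = {}
    truth: dict[str, dict] = {}
    window = ref.target_window

    if stage == "seq42":
        wt_members = tuple(["WT"] * wt_pool_size)
        wt_pool = PoolSpec("wt_source", wt_members, stage="seq42")
        wt_source = simulate_pool_reads(
            wt_pool, genotypes, error, coverage, seed=int(rng.integers(2**31 - 1))
        )
        wt_control = simulate_pool_reads(
            wt_pool, genotypes, error, coverage, seed=int(rng.integers(2**31 - 1))
        )
    else:
        wt_members = tuple(["WT"] * pool_size)
        wt_control = simulate_melt_curves(
            allele_species([genotypes["WT"]] * pool_size, params=hrm_params),
            params=hrm_params,
            seed=int(rng.integers(2**31 - 1)),
            sample_id="wt_control",
        )

    for slot in range(n_pools):
        label = labels[int(order[slot])]
        genotype = mutants[slot] if slot < n_mutant_pools else None
        if genotype is not None:
            members = (genotype.plant_id,) + ("WT",) * (pool_size - 1)
        else:
            members = ("WT",) * pool_size
        if stage == "seq42":
            spec = PoolSpec(label, members, stage="seq42")
            undiluted = simulate_pool_reads(
                spec, genotypes, error, coverage, seed=int(rng.integers(2**31 - 1))
            )
            diluted = dilute_reads(
                undiluted, wt_source, dilution_factor, seed=int(rng.integers(2**31 - 1))
            )
            pools[label] = (undiluted, diluted)
        else:
            curves = simulate_melt_curves(
                allele_species(
                    [genotypes[m] for m in members], params=hrm_params
                ),
                params=hrm_params,
                seed=int(rng.integers(2**31 - 1)),
                sample_id=label,
            )
            pools[label] = curves
        truth[label] = _pool_truth(label, genotype, window)

    params = {
        "pool_size": pool_size,
        "coverage": coverage,
        "substitution_rate": error.substitution_rate,
        "indel_error_rate": error.indel_error_rate,
        "dilution_factor": dilution_factor,
        "wt_pool_size": wt_pool_size,
        "tm_wt": hrm_params.tm_wt,
        "het_tm_shift": hrm_params.het_tm_shift,
        "noise_sd": hrm_params.noise_sd,
        "replicates": hrm_params.replicates,
    }
    manifest = Manifest(stage=stage, seed=seed, pools=truth, params=params)
    return BlindSet(
        stage=stage,
        pools=dict(sorted(pools.items())),
        wt_control=wt_control,
        manifest=manifest,
        genotypes=genotypes,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_blind_set(blind: BlindSet, outdir) -> Path:
    """Write a blind set's fixtures plus its manifest (with checksums)."""
    from .hrm import write_melt_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    if blind.stage == "seq42":
        for label, (undiluted, diluted) in blind.pools.items():
            for suffix, rs in (("undiluted", undiluted), ("diluted", diluted)):
                p = outdir / f"{label}_{suffix}.fastq"
                rs.to_fastq(p)
                files[p.name] = _sha256(p)
        p = outdir / "wt_control.fastq"
        blind.wt_control.to_fastq(p)
        files[p.name] = _sha256(p)
    else:
        p = outdir / "melt_curves.csv"
        write_melt_csv(p, *blind.pools.values(), blind.wt_control)
        files[p.name] = _sha256(p)
    blind.manifest.files = files
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(blind.manifest.to_json())
    return manifest_path
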