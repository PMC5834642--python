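"""The full hierarchical screen: sequencing pools, HRM pools, 1:1 confirmation.

Shoots regenerated without selection are screened in three stages of group
testing: (1) 42-plant pools analyzed by pooled amplicon sequencing with the
dilution-contrast NVF call; (2) positive pools split into 7-plant pools
classified by HRM difference curves; (3) each plant of a positive 7-plant
pool confirmed by HRM of a 1:1 mix with a wild-type plant.  Confirmed
mutants are then described allele by allele and classified as transgenic or
non-transgenic by the three-primer-set T-DNA assay.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hrm import HRMCall, classify_hrm, confirm_individual, difference_curve
from .mutations import MutationDescription, describe_allele
from .nvf import (
    Baseline,
    CallParams,
    DilutionPair,
    PoolCall,
    compute_nvf,
    dilution_contrast_call,
    estimate_baseline,
)
from .pcr import TDNA_PRIMER_SETS, classify_transgene, genome_sequences, synthetic_tdna_regions
from .plants import PlantGenotype, wild_type_genotype
from .reference import REFERENCE, ReferenceAmplicon
from .simulate import (
    ErrorModel,
    HRMParams,
    PoolSpec,
    allele_species,
    dilute_reads,
    simulate_melt_curves,
    simulate_pool_reads,
)

__all__ = [
    "ScreenPlan",
    "ScreenParams",
    "MutantRecord",
    "ScreenReport",
    "plan_pools",
    "run_screen",
    "efficiency_report",
    "efficiency_table",
    "round_half_up",
]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (the arithmetic used in the printed tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ScreenPlan:
    """Deterministic assignment of plants to stage-1 pools (by plant order)
    and the stage-2 split rule."""

    plant_ids: tuple[str, ...]
    stage1_pool_size: int = 42
    stage2_pool_size: int = 7

    def __post_init__(self) -> None:
        if not self.plant_ids:
            raise ValueError("a screen needs at least one plant")
        if self.stage2_pool_size > self.stage1_pool_size:
            raise ValueError("stage-2 pools cannot exceed stage-1 pools in size")
        if self.stage1_pool_size < 1 or self.stage2_pool_size < 1:
            raise ValueError("pool sizes must be >= 1")

    @property
    def n_shoots(self) -> int:
        return len(self.plant_ids)

    @property
    def stage1_pools(self) -> tuple[tuple[str, ...], ...]:
        s = self.stage1_pool_size
        ids = self.plant_ids
        return tuple(
            tuple(ids[i : i + s]) for i in range(0, len(ids), s)
        )

    def stage2_split(self, pool_index: int) -> tuple[tuple[str, ...], ...]:
        """Partition one stage-1 pool into stage-2 pools."""
        members = self.stage1_pools[pool_index]
        s = self.stage2_pool_size
        return tuple(
            tuple(members[i : i + s]) for i in range(0, len(members), s)
        )

    @property
    def n_stage1_pools(self) -> int:
        return math.ceil(self.n_shoots / self.stage1_pool_size)


def plan_pools(
    plants: int | Sequence[str],
    stage1_pool_size: int = 42,
    stage2_pool_size: int = 7,
) -> ScreenPlan:
    """Build a screen plan from a shoot count or explicit plant ids."""
    if isinstance(plants, int):
        if plants < 1:
            raise ValueError("n_shoots must be >= 1")
        ids = tuple(f"plant_{i + 1:04d}" for i in range(plants))
    else:
        ids = tuple(plants)
    return ScreenPlan(ids, stage1_pool_size, stage2_pool_size)


@dataclass(frozen=True)
class ScreenParams:
    """Everything the simulated screen needs besides the genotypes."""

    coverage: int = 20_000
    error: ErrorModel = field(default_factory=ErrorModel)
    hrm: HRMParams = field(default_factory=HRMParams)
    call: CallParams = field(default_factory=CallParams)
    k_sd: float = 5.0
    dilution_factor: float = 6.0
    wt_pool_size: int = 84
    seed: int = 0


@dataclass(frozen=True)
class MutantRecord:
    """A confirmed mutant with its mutation descriptions and T-DNA status."""

    plant_id: str
    descriptions: tuple[tuple[MutationDescription, ...], ...]  # per allele
    transgenic: str  # "transgenic" | "non-transgenic"
    stage1_pool: int
    stage2_pool: tuple[int, int]

    @property
    def description_texts(self) -> tuple[str, ...]:
        return tuple(d.text for allele in self.descriptions for d in allele)


@dataclass
class ScreenReport:
    """End-to-end result of a simulated screen."""

    plan: ScreenPlan
    stage1_calls: list[PoolCall]
    stage2_calls: dict[int, list[HRMCall]]
    stage3_calls: dict[str, HRMCall]
    mutants: list[MutantRecord]
    unresolved_stage1: list[int]
    assay_counts: dict[str, int]

    @property
    def mutant_ids(self) -> tuple[str, ...]:
        return tuple(sorted(m.plant_id for m in self.mutants))

    def trace(self, plant_id: str) -> dict:
        """Audit trail: the positive calls that led to a reported mutant."""
        record = next(m for m in self.mutants if m.plant_id == plant_id)
        s2_pool, s2_sub = record.stage2_pool
        return {
            "stage1_pool": record.stage1_pool,
            "stage1_positive": self.stage1_calls[record.stage1_pool].positive,
            "stage2_pool": record.stage2_pool,
            "stage2_positive": self.stage2_calls[s2_pool][s2_sub].positive,
            "stage3_positive": self.stage3_calls[plant_id].positive,
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_shoots": self.plan.n_shoots,
                "assay_counts": self.assay_counts,
                "stage1": [
                    {
                        "pool": i,
                        "positive": c.positive,
                        "locus": c.locus_text,
                    }
                    for i, c in enumerate(self.stage1_calls)
                ],
                "unresolved_stage1": self.unresolved_stage1,
                "mutants": [
                    {
                        "plant_id": m.plant_id,
                        "mutations": [
                            [d.text for d in allele] for allele in m.descriptions
                        ],
                        "transgenic": m.transgenic,
                    }
                    for m in self.mutants
                ],
            },
            indent=2,
        )

    def summary_table(self) -> pd.DataFrame:
        rows = [
            {
                "plant_id": m.plant_id,
                "mutations": "; ".join(dict.fromkeys(m.description_texts)),
                "transgenic": m.transgenic,
            }
            for m in self.mutants
        ]
        return pd.DataFrame(rows, columns=["plant_id", "mutations", "transgenic"])


def run_screen(
    genotypes: Mapping[str, PlantGenotype],
    plan: ScreenPlan | None = None,
    params: ScreenParams | None = None,
    ref: ReferenceAmplicon = REFERENCE,
) -> ScreenReport:
    """Run the three-stage screen on a simulated cohort.

    ``genotypes`` maps every shoot to its genotype (wild-type plants
    included).  Stage-1 libraries (undiluted plus 1:factor diluted) are
    simulated per pool, called by the NVF dilution contrast against a
    wild-type baseline, and positive pools are deconvolved by simulated HRM
    at stage 2 and confirmed 1:1 at stage 3.
    """
    params = params or ScreenParams()
    plan = plan or plan_pools(sorted(genotypes))
    missing = [p for p in plan.plant_ids if p not in genotypes]
    if missing:
        raise KeyError(f"no genotype for planned plants: {missing[:5]}")
    rng = np.random.default_rng(params.seed)

    def next_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    wt = wild_type_genotype("__wt_reference__", ref)
    aug = dict(genotypes)
    aug[wt.plant_id] = wt

    # shared wild-type libraries: dilution source and baseline control
    wt_members = (wt.plant_id,) * params.wt_pool_size
    wt_spec = PoolSpec("wt_source", wt_members, stage="seq42")
    wt_source = simulate_pool_reads(
        wt_spec, aug, params.error, params.coverage, seed=next_seed()
    )
    wt_control = simulate_pool_reads(
        wt_spec, aug, params.error, params.coverage, seed=next_seed()
    )
    baseline = estimate_baseline(wt_control, ref)

    assay_counts = {"stage1_libraries": 0, "stage2_hrm": 0, "stage3_hrm": 0}

    stage1_calls: list[PoolCall] = []
    for i, members in enumerate(plan.stage1_pools):
        spec = PoolSpec(f"stage1_{i}", tuple(members), stage="seq42")
        undiluted = simulate_pool_reads(
            spec, aug, params.error, params.coverage, seed=next_seed()
        )
        diluted = dilute_reads(
            undiluted, wt_source, params.dilution_factor, seed=next_seed()
        )
        pair = DilutionPair(
            compute_nvf(undiluted, ref),
            compute_nvf(diluted, ref),
            factor=params.dilution_factor,
        )
        stage1_calls.append(
            dilution_contrast_call(pair, baseline, params.call, pool_id=spec.pool_id)
        )
        assay_counts["stage1_libraries"] += 2

    stage2_calls: dict[int, list[HRMCall]] = {}
    stage3_calls: dict[str, HRMCall] = {}
    mutants: list[MutantRecord] = []
    unresolved: list[int] = []
    tdna_regions = synthetic_tdna_regions()

    for i, call in enumerate(stage1_calls):
        if not call.positive:
            continue
        subpools = plan.stage2_split(i)
        calls_here: list[HRMCall] = []
        for j, members in enumerate(subpools):
            composition = allele_species(
                [aug[m] for m in members], params=params.hrm
            )
            curves = simulate_melt_curves(
                composition,
                params=params.hrm,
                seed=next_seed(),
                sample_id=f"stage2_{i}_{j}",
            )
            wt_curves = simulate_melt_curves(
                allele_species([wt] * len(members), params=params.hrm),
                params=params.hrm,
                seed=next_seed(),
                sample_id=f"stage2_{i}_{j}_wt",
            )
            calls_here.append(
                classify_hrm(difference_curve(curves, wt_curves), k=params.k_sd)
            )
            assay_counts["stage2_hrm"] += 1
        stage2_calls[i] = calls_here
        if not any(c.positive for c in calls_here):
            unresolved.append(i)
            continue
        for j, hrm_call in enumerate(calls_here):
            if not hrm_call.positive:
                continue
            for plant_id in subpools[j]:
                confirmation = confirm_individual(
                    aug[plant_id], wt, params=params.hrm, seed=next_seed(), k=params.k_sd
                )
                stage3_calls[plant_id] = confirmation
                assay_counts["stage3_hrm"] += 1
                if not confirmation.positive:
                    continue
                genotype = aug[plant_id]
                descriptions = tuple(
                    tuple(describe_allele(allele, ref))
                    for allele in genotype.alleles
                )
                status = classify_transgene(
                    genome_sequences(genotype, tdna_regions), TDNA_PRIMER_SETS
                )
                mutants.append(
                    MutantRecord(
                        plant_id=plant_id,
                        descriptions=descriptions,
                        transgenic=status,
                        stage1_pool=i,
                        stage2_pool=(i, j),
                    )
                )

    return ScreenReport(
        plan=plan,
        stage1_calls=stage1_calls,
        stage2_calls=stage2_calls,
        stage3_calls=stage3_calls,
        mutants=mutants,
        unresolved_stage1=unresolved,
        assay_counts=assay_counts,
    )


# ---------------------------------------------------------------------------
# efficiency arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EfficiencySummary:
    """Percentages recomputed from integer counts, half-up to 1 decimal.

    ``non_transgenic_pct`` and ``overall_rate_pct`` are ``None`` when their
    denominators are zero (explicit undefined, not NaN)."""

    explants: int
    mutant_shoots: int
    characterized: int
    non_transgenic: int
    mutation_efficiency_pct: float | None
    non_transgenic_pct: float | None
    overall_rate_pct: float | None


def efficiency_report(
    explants: int,
    mutant_shoots: int,
    characterized: int = 0,
    non_transgenic: int = 0,
) -> EfficiencySummary:
    """Mutation efficiency, non-transgenic fraction and the overall rate.

    mutation efficiency = 100 * mutant_shoots / explants;
    non-transgenic fraction = 100 * non_transgenic / characterized;
    overall rate = their product as a percentage.  All half-up to 1 decimal.
    """
    for name, v in (
        ("explants", explants),
        ("mutant_shoots", mutant_shoots),
        ("characterized", characterized),
        ("non_transgenic", non_transgenic),
    ):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer")
    if characterized > mutant_shoots:
        raise ValueError("characterized mutants cannot exceed mutant shoots")
    if non_transgenic > characterized:
        raise ValueError("non-transgenic mutants cannot exceed characterized")
    efficiency = (
        round_half_up(100.0 * mutant_shoots / explants) if explants else None
    )
    non_t = (
        round_half_up(100.0 * non_transgenic / characterized)
        if characterized
        else None
    )
    overall = (
        round_half_up(
            100.0 * (mutant_shoots / explants) * (non_transgenic / characterized)
        )
        if explants and characterized
        else None
    )
    return EfficiencySummary(
        explants=explants,
        mutant_shoots=mutant_shoots,
        characterized=characterized,
        non_transgenic=non_transgenic,
        mutation_efficiency_pct=efficiency,
        non_transgenic_pct=non_t,
        overall_rate_pct=overall,
    )


def efficiency_table(
    per_experiment: Sequence[tuple[int, int]],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-experiment mutation efficiencies plus a totals row."""
    labels = labels or [str(i + 1) for i in range(len(per_experiment))]
    rows = []
    for label, (explants, mutants) in zip(labels, per_experiment):
        rows.append(
            {
                "experiment": label,
                "explants": explants,
                "mutant_shoots": mutants,
                "efficiency_pct": round_half_up(100.0 * mutants / explants)
                if explants
                else None,
            }
        )
    total_e = sum(e for e, _ in per_experiment)
    total_m = sum(m for _, m in per_experiment)
    rows.append(
        {
            "experiment": "Total",
            "explants": total_e,
            "mutant_shoots": total_m,
            "efficiency_pct": round_half_up(100.0 * total_m / total_e)
            if total_e
            else None,
        }
    )
    return pd.DataFrame(rows)
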