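"""High-resolution melting (HRM) curve analysis.

Pools that survive the sequencing screen are deconvolved by melt-curve
genotyping: amplicons from a pool containing a mutant form heteroduplexes on
reannealing, which melt a couple of degrees earlier than homoduplexes and
deform the fluorescence-vs-temperature curve.  Curves are normalized to a
0..1 fluorescence scale using pre- and post-melt windows, averaged over
replicates, and compared to a wild-type reference as a difference curve;
a pool is called positive when the maximum absolute difference exceeds a
multiple of the replicate noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MeltCurveError",
    "MeltCurveSet",
    "DifferenceCurve",
    "HRMCall",
    "normalize_melt",
    "difference_curve",
    "classify_hrm",
    "confirm_individual",
    "read_melt_csv",
    "write_melt_csv",
]

#: Default normalization windows (degrees C): fully annealed / fully melted.
PRE_MELT_WINDOW = (70.0, 75.0)
POST_MELT_WINDOW = (90.0, 95.0)


class MeltCurveError(ValueError):
    """Raised for degenerate or incompatible melt curves."""


@dataclass(frozen=True)
class MeltCurveSet:
    """Replicate fluorescence traces of one sample on a shared grid.

    ``rfu`` has shape ``(n_replicates, n_temperatures)``.
    """

    sample_id: str
    temperatures: np.ndarray
    rfu: np.ndarray

    def __post_init__(self) -> None:
        temps = np.asarray(self.temperatures, dtype=float)
        rfu = np.atleast_2d(np.asarray(self.rfu, dtype=float))
        if temps.ndim != 1 or np.any(np.diff(temps) <= 0):
            raise MeltCurveError("temperature grid must be strictly increasing")
        if rfu.shape[1] != temps.size:
            raise MeltCurveError("rfu and temperature grids differ in length")
        if not np.all(np.isfinite(rfu)):
            raise MeltCurveError("rfu values must be finite")
        object.__setattr__(self, "temperatures", temps)
        object.__setattr__(self, "rfu", rfu)

    @property
    def n_replicates(self) -> int:
        return self.rfu.shape[0]

    def mean(self) -> np.ndarray:
        return self.rfu.mean(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rep in range(self.n_replicates):
            rows.append(
                pd.DataFrame(
                    {
                        "temperature_C": self.temperatures,
                        "rfu": self.rfu[rep],
                        "replicate": rep + 1,
                        "sample_id": self.sample_id,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class DifferenceCurve:
    """Replicate-averaged normalized sample minus the WT reference."""

    sample_id: str
    temperatures: np.ndarray
    delta_rfu: np.ndarray
    replicate_sd: np.ndarray


@dataclass(frozen=True)
class HRMCall:
    """Classification of one difference curve."""

    sample_id: str
    positive: bool
    statistic: float  # max |delta_rfu| over the grid
    threshold: float


def _window_mean(temps: np.ndarray, values: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    mask = (temps >= lo) & (temps <= hi)
    if not mask.any():
        raise MeltCurveError(f"normalization window {window} outside the grid")
    return values[..., mask].mean(axis=-1)


def normalize_melt(
    curves: MeltCurveSet,
    pre_window: tuple[float, float] = PRE_MELT_WINDOW,
    post_window: tuple[float, float] = POST_MELT_WINDOW,
) -> MeltCurveSet:
    """Linearly rescale each replicate so the pre-melt window has mean 1 and
    the post-melt window mean 0.  A monotone (affine) transformation only;
    idempotent on already-normalized curves."""
    if pre_window[1] >= post_window[0]:
        raise MeltCurveError("pre- and post-melt windows must not overlap")
    pre = _window_mean(curves.temperatures, curves.rfu, pre_window)
    post = _window_mean(curves.temperatures, curves.rfu, post_window)
    span = pre - post
    if np.any(np.abs(span) < 1e-12):
        raise MeltCurveError(
            f"degenerate curve for {curves.sample_id!r}: zero pre/post-melt range"
        )
    rfu = (curves.rfu - post[:, None]) / span[:, None]
    return MeltCurveSet(curves.sample_id, curves.temperatures, rfu)


def difference_curve(
    samples: MeltCurveSet,
    reference: MeltCurveSet,
    normalize: bool = True,
    pre_window: tuple[float, float] = PRE_MELT_WINDOW,
    post_window: tuple[float, float] = POST_MELT_WINDOW,
) -> DifferenceCurve:
    """Replicate-mean sample minus replicate-mean WT reference.

    Both curve sets must share the temperature grid; per-temperature
    replicate standard deviation of the sample differences is retained for
    classification.
    """
    if samples.temperatures.shape != reference.temperatures.shape or np.any(
        samples.temperatures != reference.temperatures
    ):
        raise MeltCurveError("sample and reference grids differ")
    if normalize:
        samples = normalize_melt(samples, pre_window, post_window)
        reference = normalize_melt(reference, pre_window, post_window)
    ref_mean = reference.mean()
    deltas = samples.rfu - ref_mean[None, :]
    sd = (
        deltas.std(axis=0, ddof=1)
        if samples.n_replicates > 1
        else np.zeros_like(ref_mean)
    )
    return DifferenceCurve(
        sample_id=samples.sample_id,
        temperatures=samples.temperatures,
        delta_rfu=deltas.mean(axis=0),
        replicate_sd=sd,
    )


def classify_hrm(diff: DifferenceCurve, k: float = 5.0) -> HRMCall:
    """Call a sample positive when ``max |delta| > k * median(replicate SD)``.

    With a degenerate noise model (all-zero replicate SD) any nonzero
    deviation is positive, with a warning.
    """
    statistic = float(np.max(np.abs(diff.delta_rfu)))
    noise = float(np.median(diff.replicate_sd))
    threshold = k * noise
    if noise == 0.0 and statistic > 0.0:
        warnings.warn(
            f"{diff.sample_id!r}: zero replicate SD with nonzero difference; "
            "noise model degenerate, calling positive",
            stacklevel=2,
        )
        return HRMCall(diff.sample_id, True, statistic, threshold)
    return HRMCall(diff.sample_id, statistic > threshold, statistic, threshold)


def confirm_individual(
    candidate,
    wt,
    params=None,
    seed: int = 0,
    k: float = 5.0,
) -> HRMCall:
    """Confirm a putative mutant by a simulated 1:1 mix with a WT plant.

    Simulates triplicate melt curves for an equal-tissue mix of the
    candidate and a wild-type plant, plus a WT-only reference, and
    classifies the difference curve.  Even a mutant homozygous for one
    indel across all four alleles forms heteroduplexes in the 1:1 mix.
    """
    from .simulate import HRMParams, allele_species, simulate_melt_curves

    if params is None:
        params = HRMParams()
    rng = np.random.default_rng(seed)
    mix_seed, ref_seed = (int(s) for s in rng.integers(0, 2**31 - 1, 2))
    mix = simulate_melt_curves(
        allele_species([candidate, wt], params=params),
        params=params,
        seed=mix_seed,
        sample_id=f"{candidate.plant_id}+WT",
    )
    reference = simulate_melt_curves(
        allele_species([wt, wt], params=params),
        params=params,
        seed=ref_seed,
        sample_id="WT_reference",
    )
    return classify_hrm(difference_curve(mix, reference), k=k)


# ---------------------------------------------------------------------------
# CSV interface (columns: temperature_C, rfu, replicate, sample_id)
# ---------------------------------------------------------------------------

def write_melt_csv(path, *curve_sets: MeltCurveSet) -> None:
    df = pd.concat([c.to_dataframe() for c in curve_sets], ignore_index=True)
    df.to_csv(path, index=False)


def read_melt_csv(path) -> dict[str, MeltCurveSet]:
    """Read melt curves; returns one :class:`MeltCurveSet` per sample_id."""
    df = pd.read_csv(path)
    required = {"temperature_C", "rfu", "replicate", "sample_id"}
    if not required.issubset(df.columns):
        raise MeltCurveError(f"melt CSV must have columns {sorted(required)}")
    out: dict[str, MeltCurveSet] = {}
    for sample_id, group in df.groupby("sample_id", sort=False):
        reps = sorted(group["replicate"].unique())
        grids = []
        rfu = []
        for rep in reps:
            sub = group[group["replicate"] == rep].sort_values("temperature_C")
            grids.append(sub["temperature_C"].to_numpy())
            rfu.append(sub["rfu"].to_numpy())
        for g in grids[1:]:
            if g.shape != grids[0].shape or np.any(g != grids[0]):
                raise MeltCurveError(f"replicate grids differ for {sample_id!r}")
        out[str(sample_id)] = MeltCurveSet(str(sample_id), grids[0], np.vstack(rfu))
    return out
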