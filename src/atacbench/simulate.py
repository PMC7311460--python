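"""Parameterized simulator for ATAC-seq peak-count matrices with ground truth.

The simulator emulates a two-condition ATAC-seq experiment at the level of
read counts under a fixed set of peaks (no genomic coordinates, no read-level
structure).  Peaks fall into signal-density tiers (nominal counts-per-million,
CPM) and difference classes (relative excess of the high condition over the
low condition).  The two condition means of a differentially accessible peak
are constrained to average to the tier's nominal density:

    low = 2 * nominal / (2 + f),    high = low * (1 + f)

so that a tier-5-CPM peak with a 50% mean difference has condition means of
4 and 6 CPM.  Replicate densities are drawn from a normal distribution whose
standard deviation is a fixed fraction of that condition's own mean, then
converted to integer counts at a chosen effective sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TierSpec",
    "DifferenceClass",
    "SimulationDesign",
    "LabeledCountMatrix",
    "DEFAULT_TIERS",
    "DEFAULT_CLASSES",
    "resolve_condition_means",
    "compute_peak_count",
    "simulate_counts",
    "simulate_repeats",
    "batch_inject",
]


@dataclass(frozen=True)
class TierSpec:
    """One signal-density tier: nominal density (CPM) and its share of peaks."""

    nominal_cpm: float
    proportion: float

    def __post_init__(self) -> None:
        if self.nominal_cpm <= 0:
            raise ValueError(f"nominal_cpm must be > 0, got {self.nominal_cpm}")
        if not 0 < self.proportion <= 1:
            raise ValueError(f"tier proportion must be in (0, 1], got {self.proportion}")


@dataclass(frozen=True)
class DifferenceClass:
    """One mean-difference class; fraction 0 is the true-negative class."""

    mean_diff_fraction: float
    proportion: float

    def __post_init__(self) -> None:
        if self.mean_diff_fraction < 0:
            raise ValueError("mean_diff_fraction must be >= 0")
        if not 0 < self.proportion <= 1:
            raise ValueError("class proportion must be in (0, 1]")


DEFAULT_TIERS = (
    TierSpec(nominal_cpm=1.0, proportion=0.60),
    TierSpec(nominal_cpm=5.0, proportion=0.30),
    TierSpec(nominal_cpm=10.0, proportion=0.10),
)

DEFAULT_CLASSES = (
    DifferenceClass(0.0, 0.80),
    DifferenceClass(0.10, 0.05),
    DifferenceClass(0.20, 0.05),
    DifferenceClass(0.50, 0.05),
    DifferenceClass(1.00, 0.05),
)


@dataclass(frozen=True)
class SimulationDesign:
    """Full parameterization of one simulated two-condition experiment.

    Parameters
    ----------
    tiers, classes
        Signal tiers and mean-difference classes; proportions must each sum
        to 1 (within 1e-9).
    depth
        Effective reads under peaks per sample (the CPM denominator).
    sd_fraction
        In-group standard deviation as a fraction of each condition's mean.
    replicates_per_condition
        Number of replicates simulated per condition; down-sampling studies
        subset the leading columns.
    n_repeats
        Number of independent simulated files for repeat aggregation.
    seed
        Base RNG seed; repeat ``i`` uses ``SeedSequence([seed, i])``.
    n_peaks
        Optional override of the derived peak count.
    """

    tiers: tuple[TierSpec, ...] = DEFAULT_TIERS
    classes: tuple[DifferenceClass, ...] = DEFAULT_CLASSES
    depth: float = 30e6
    sd_fraction: float = 0.10
    replicates_per_condition: int = 3
    n_repeats: int = 1
    seed: int = 0
    n_peaks: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tiers", tuple(self.tiers))
        object.__setattr__(self, "classes", tuple(self.classes))
        if not self.tiers:
            raise ValueError("at least one tier is required")
        if not self.classes:
            raise ValueError("at least one difference class is required")
        for name, specs in (("tier", self.tiers), ("class", self.classes)):
            total = sum(s.proportion for s in specs)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1, got {total}")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0 < self.sd_fraction < 1:
            raise ValueError("sd_fraction must be in (0, 1)")
        if self.replicates_per_condition < 2:
            raise ValueError("replicates_per_condition must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    @property
    def total_peaks(self) -> int:
        return self.n_peaks if self.n_peaks is not None else compute_peak_count(self.tiers)


@dataclass
class LabeledCountMatrix:
    """Peaks x samples integer counts with per-peak ground-truth labels.

    ``truth`` has columns ``tier_cpm``, ``mean_diff`` and ``direction``
    (+1: condition A higher, -1: condition B higher, 0: true negative),
    indexed by peak id.  ``design`` has one row per sample with columns
    ``condition`` and ``batch``.
    """

    counts: np.ndarray
    peak_ids: np.ndarray
    samples: np.ndarray
    condition: np.ndarray
    truth: pd.DataFrame
    batch: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.batch is None:
            self.batch = np.zeros(len(self.samples), dtype=int)
        if self.counts.shape != (len(self.peak_ids), len(self.samples)):
            raise ValueError("counts shape does not match peak/sample labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def design(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"condition": self.condition, "batch": self.batch},
            index=pd.Index(self.samples, name="sample"),
        )

    def group_mask(self, cond: str) -> np.ndarray:
        return self.condition == cond

    def subset_replicates(self, k: int) -> "LabeledCountMatrix":
        """Keep the first ``k`` replicates of each condition (prefix rule)."""
        keep = np.concatenate(
            [np.flatnonzero(self.condition == c)[:k] for c in ("A", "B")]
        )
        if len(keep) != 2 * k:
            raise ValueError(f"cannot subset to {k} replicates per condition")
        return LabeledCountMatrix(
            counts=self.counts[:, keep],
            peak_ids=self.peak_ids,
            samples=self.samples[keep],
            condition=self.condition[keep],
            truth=self.truth,
            batch=self.batch[keep],
        )


def resolve_condition_means(nominal_cpm: float, mean_diff_fraction: float) -> tuple[float, float]:
    """Split a tier's nominal density into the two condition means.

    The two condition means average to ``nominal_cpm`` and the high condition
    exceeds the low by ``mean_diff_fraction``; in closed form
    ``low = 2 * nominal / (2 + f)`` and ``high = low * (1 + f)``.
    """
    if nominal_cpm <= 0:
        raise ValueError("nominal_cpm must be > 0")
    if mean_diff_fraction < 0:
        raise ValueError("mean_diff_fraction must be >= 0")
    low = 2.0 * nominal_cpm / (2.0 + mean_diff_fraction)
    high = low * (1.0 + mean_diff_fraction)
    return low, high


def compute_peak_count(tiers) -> int:
    """Number of peaks so that the expected total density is 1e6 CPM.

    N = round(1e6 / sum_t proportion_t * nominal_cpm_t); with the default
    60/30/10% mix at 1/5/10 CPM this gives 322,581 peaks.
    """
    tiers = tuple(tiers)
    if not tiers:
        raise ValueError("empty tier list")
    mean_cpm = sum(t.proportion * t.nominal_cpm for t in tiers)
    return int(round(1e6 / mean_cpm))


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``targets`` (sum==total)."""
    raw = targets / targets.sum() * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    # deterministic tie-break: largest fractional part, then lowest index
    order = np.lexsort((np.arange(len(raw)), -(raw - base)))
    base[order[:short]] += 1
    return base


def _truth_table(design: SimulationDesign) -> pd.DataFrame:
    """Deterministic peak-level truth: tier, mean difference, direction.

    Peak counts per tier x class cell follow the design proportions exactly
    (largest-remainder rounding); within each true-positive cell half the
    peaks are higher in condition A and half in condition B.
    """
    n = design.total_peaks
    cells = [(t, c) for t in design.tiers for c in design.classes]
    targets = np.array([t.proportion * c.proportion for t, c in cells])
    alloc = _largest_remainder(targets, n)

    tier_cpm = np.empty(n)
    mean_diff = np.empty(n)
    direction = np.zeros(n, dtype=int)
    pos = 0
    for (tier, cls), size in zip(cells, alloc):
        sl = slice(pos, pos + size)
        tier_cpm[sl] = tier.nominal_cpm
        mean_diff[sl] = cls.mean_diff_fraction
        if cls.mean_diff_fraction > 0:
            n_a = size // 2
            direction[pos : pos + n_a] = 1
            direction[pos + n_a : pos + size] = -1
        pos += size
    peak_ids = np.array([f"peak_{i:07d}" for i in range(n)])
    return pd.DataFrame(
        {"tier_cpm": tier_cpm, "mean_diff": mean_diff, "direction": direction},
        index=pd.Index(peak_ids, name="peak_id"),
    )


def simulate_counts(design: SimulationDesign, repeat: int = 0) -> LabeledCountMatrix:
    """Simulate one labeled peak-count matrix under ``design``.

    Per-replicate densities are drawn from Normal(mean, sd_fraction * mean)
    per condition, converted to counts as ``cpm * depth / 1e6``, rounded to
    the nearest integer and clamped at zero.  The same (seed, repeat) pair
    always yields a bit-identical matrix.
    """
    truth = _truth_table(design)
    n = len(truth)
    r = design.replicates_per_condition

    tier = truth["tier_cpm"].to_numpy()
    f = truth["mean_diff"].to_numpy()
    low = 2.0 * tier / (2.0 + f)
    high = low * (1.0 + f)
    direction = truth["direction"].to_numpy()
    mean_a = np.where(direction >= 0, np.where(direction > 0, high, tier), low)
    mean_b = np.where(direction >= 0, np.where(direction > 0, low, tier), high)

    rng = np.random.default_rng(np.random.SeedSequence([design.seed, repeat]))
    means = np.concatenate(
        [np.repeat(mean_a[:, None], r, axis=1), np.repeat(mean_b[:, None], r, axis=1)],
        axis=1,
    )
    cpm = rng.normal(loc=means, scale=design.sd_fraction * means)
    counts = np.rint(np.clip(cpm, 0.0, None) * design.depth / 1e6).astype(np.int64)

    samples = np.array([f"A{i + 1}" for i in range(r)] + [f"B{i + 1}" for i in range(r)])
    condition = np.array(["A"] * r + ["B"] * r)
    return LabeledCountMatrix(
        counts=counts,
        peak_ids=truth.index.to_numpy(),
        samples=samples,
        condition=condition,
        truth=truth,
    )


def simulate_repeats(design: SimulationDesign):
    """Yield ``design.n_repeats`` independent matrices (derived sub-seeds)."""
    for i in range(design.n_repeats):
        yield simulate_counts(design, repeat=i)


def batch_inject(
    matrix: LabeledCountMatrix,
    batches: dict[str, int] | np.ndarray,
    batch_effect_size: float,
    seed: int = 0,
    affected_batch: int | None = None,
    spread: float = 0.6,
) -> LabeledCountMatrix:
    """Overlay a multiplicative batch effect on one batch of samples.

    Counts of samples in ``affected_batch`` (default: the highest batch
    label) are scaled by a peak-specific factor drawn around
    ``batch_effect_size``: factor = 1 + (size - 1) * g with
    g ~ Normal(1, spread) clipped at 0, so size 1 leaves the matrix
    unchanged.  Truth labels are untouched.
    """
    if batch_effect_size <= 0:
        raise ValueError("batch_effect_size must be > 0")
    if isinstance(batches, dict):
        missing = [s for s in matrix.samples if s not in batches]
        if missing:
            raise KeyError(f"samples missing a batch assignment: {missing}")
        unknown = [s for s in batches if s not in set(matrix.samples)]
        if unknown:
            raise KeyError(f"unknown sample id(s): {unknown}")
        batch = np.array([batches[s] for s in matrix.samples], dtype=int)
    else:
        batch = np.asarray(batches, dtype=int)
        if batch.shape != matrix.samples.shape:
            raise ValueError("batch assignment length does not match samples")
    if affected_batch is None:
        affected_batch = int(batch.max())

    rng = np.random.default_rng(seed)
    g = np.clip(rng.normal(1.0, spread, size=len(matrix.peak_ids)), 0.0, None)
    factor = 1.0 + (batch_effect_size - 1.0) * g
    counts = matrix.counts.astype(float).copy()
    cols = np.flatnonzero(batch == affected_batch)
    counts[:, cols] *= factor[:, None]
    return LabeledCountMatrix(
        counts=np.rint(np.clip(counts, 0.0, None)).astype(np.int64),
        peak_ids=matrix.peak_ids,
        samples=matrix.samples,
        condition=matrix.condition,
        truth=matrix.truth,
        batch=batch,
    )
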