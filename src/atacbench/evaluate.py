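"""Benchmark metrics for truth-labeled differential-accessibility results.

Implements the confusion-matrix bookkeeping, the two false-positive metrics
used in the field (FPR = FP/(FP+TN) and the false-discovery proportion
FP/(FP+TP)), ROC curves with AUC, and the simulate -> test -> evaluate sweep
over replicate counts with repeat aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .da import MethodSpec, run_method
from .simulate import SimulationDesign, simulate_counts

__all__ = [
    "ConfusionCounts",
    "confusion",
    "fpr",
    "recall",
    "false_discovery_proportion",
    "roc_curve",
    "auc",
    "benchmark_sweep",
    "aggregate_sweep",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def dar(self) -> int:
        """Number of truly differential peaks (TP + FN)."""
        return self.TP + self.FN


def confusion(truth_mean_diff: np.ndarray, called: np.ndarray) -> ConfusionCounts:
    """Count TP/FP/TN/FN; a peak is positive when its true mean diff > 0."""
    truth_mean_diff = np.asarray(truth_mean_diff)
    called = np.asarray(called, dtype=bool)
    if truth_mean_diff.shape != called.shape:
        raise ValueError("truth and calls are not aligned")
    pos = truth_mean_diff > 0
    return ConfusionCounts(
        TP=int((pos & called).sum()),
        FP=int((~pos & called).sum()),
        TN=int((~pos & ~called).sum()),
        FN=int((pos & ~called).sum()),
    )


def fpr(c: ConfusionCounts) -> float | None:
    """FP / (FP + TN); None (missing) when there are no true negatives."""
    denom = c.FP + c.TN
    return c.FP / denom if denom > 0 else None


def recall(c: ConfusionCounts) -> float | None:
    """TP / (TP + FN), identical to the true positive rate / sensitivity."""
    if c.dar == 0:
        return None
    return c.TP / c.dar


def false_discovery_proportion(c: ConfusionCounts) -> float | None:
    """FP / (FP + TP): share of calls that are false; None when no calls."""
    denom = c.FP + c.TP
    return c.FP / denom if denom > 0 else None


def roc_curve(pvalues: np.ndarray, truth_positive: np.ndarray) -> pd.DataFrame:
    """Sweep p-value thresholds; return monotone (fpr, recall) points.

    Tied p-values enter as a single threshold step, and the curve is
    anchored at (0, 0) and (1, 1), so the area is order-invariant.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    truth_positive = np.asarray(truth_positive, dtype=bool)
    if truth_positive.all() or (~truth_positive).all():
        raise ValueError("ROC needs at least one positive and one negative peak")
    x, y, _ = _sk_roc_curve(truth_positive, -pvalues, drop_intermediate=False)
    return pd.DataFrame({"fpr": x, "recall": y})


def auc(points: pd.DataFrame) -> float:
    """Trapezoid area under an ROC point set."""
    return float(_sk_auc(points["fpr"].to_numpy(), points["recall"].to_numpy()))


def _stratified_rows(
    truth: pd.DataFrame,
    called: np.ndarray,
    keys: dict,
    stratify: tuple[str, ...],
) -> list[dict]:
    """Per-stratum recall/FPR/FDP rows at the global call set."""
    rows = []
    strata = [("all", np.ones(len(truth), dtype=bool))]
    if stratify:
        grouped = truth.groupby(list(stratify), sort=True).indices
        for name, idx in grouped.items():
            mask = np.zeros(len(truth), dtype=bool)
            mask[idx] = True
            strata.append((name, mask))
    md = truth["mean_diff"].to_numpy()
    for name, mask in strata:
        c = confusion(md[mask], called[mask])
        row = dict(keys)
        if name == "all":
            row.update({k: "all" for k in stratify})
        else:
            vals = name if isinstance(name, tuple) else (name,)
            row.update(dict(zip(stratify, vals)))
        row.update(
            {
                "n_peaks": int(mask.sum()),
                "recall": recall(c),
                "fpr": fpr(c),
                "fdp": false_discovery_proportion(c),
                "tp": c.TP,
                "fp": c.FP,
            }
        )
        rows.append(row)
    return rows


def benchmark_sweep(
    design: SimulationDesign,
    methods: list[MethodSpec],
    replicate_counts: list[int] | None = None,
    cutoff: float = 0.05,
    stratify: tuple[str, ...] = ("tier_cpm", "mean_diff"),
    with_roc: bool = False,
) -> pd.DataFrame:
    """Simulate ``design.n_repeats`` files and score each method per stratum.

    For every repeat, replicate count (prefix subset of the generated
    replicates) and method, peaks are called at BH-adjusted p < ``cutoff``
    (one global adjustment over all peaks) and recall/FPR/FDP are recorded
    per stratum.  Fully deterministic given the design seed.
    """
    if replicate_counts is None:
        replicate_counts = [design.replicates_per_condition]
    if max(replicate_counts) > design.replicates_per_condition:
        raise ValueError("replicate count exceeds generated replicates")
    rows: list[dict] = []
    for rep_idx in range(design.n_repeats):
        matrix = simulate_counts(design, repeat=rep_idx)
        for k in replicate_counts:
            sub = matrix.subset_replicates(k)
            for spec in methods:
                result = run_method(spec, sub)
                called = result.calls(cutoff)
                keys = {
                    "repeat": rep_idx,
                    "method": spec.name,
                    "replicates": k,
                    "depth": design.depth,
                    "sd_fraction": design.sd_fraction,
                }
                new = _stratified_rows(sub.truth, called, keys, stratify)
                if with_roc:
                    pos = sub.truth["mean_diff"].to_numpy() > 0
                    pts = roc_curve(result.pvalue, pos)
                    for row in new:
                        if all(row.get(s) == "all" for s in stratify):
                            row["auc"] = auc(pts)
                rows.extend(new)
    return pd.DataFrame(rows)


def aggregate_sweep(
    sweep: pd.DataFrame,
    by: tuple[str, ...] = ("method", "replicates", "depth", "sd_fraction"),
    stratify: tuple[str, ...] = ("tier_cpm", "mean_diff"),
) -> pd.DataFrame:
    """Mean and SD of recall/FPR over repeats for each stratum."""
    keys = list(by) + list(stratify)
    agg = (
        sweep.groupby(keys, dropna=False, sort=True)
        .agg(
            mean_recall=("recall", "mean"),
            sd_recall=("recall", "std"),
            mean_fpr=("fpr", "mean"),
            sd_fpr=("fpr", "std"),
            mean_fdp=("fdp", "mean"),
            n_repeats=("repeat", "nunique"),
        )
        .reset_index()
    )
    if "auc" in sweep.columns:
        auc_agg = (
            sweep.dropna(subset=["auc"])
            .groupby(keys, dropna=False, sort=True)["auc"]
            .mean()
            .rename("mean_auc")
            .reset_index()
        )
        agg = agg.merge(auc_agg, on=keys, how="left")
    return agg
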