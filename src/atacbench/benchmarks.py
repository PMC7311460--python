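"""Canonical benchmark scenarios over the default simulation design.

These convenience drivers wrap simulate -> test -> evaluate for the three
study conditions the package is built around: the default 3-replicate
design at 30M effective reads and 10% in-group SD, the replicate
down-sampling sweep for the rank-sum test, and the high-noise (20% SD)
6-replicate design.  Results come back as tidy per-file DataFrames ready
for aggregation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .da import MethodSpec, run_method
from .evaluate import confusion, fpr, recall
from .simulate import SimulationDesign, simulate_counts

__all__ = [
    "score_default_design",
    "wilcoxon_replicate_sweep",
    "high_noise_ttest_recall",
]


def _score_file(matrix, methods, cutoff: float = 0.05) -> list[dict]:
    md = matrix.truth["mean_diff"].to_numpy()
    rows = []
    for spec in methods:
        res = run_method(spec, matrix)
        called = res.calls(cutoff)
        overall = confusion(md, called)
        row = {
            "method": spec.name,
            "fpr": fpr(overall),
            "recall": recall(overall),
        }
        for f in sorted(set(md[md > 0])):
            mask = md == f
            row[f"recall_{int(round(f * 100))}"] = recall(confusion(md[mask], called[mask]))
        rows.append(row)
    return rows


def score_default_design(
    seed: int,
    n_files: int = 5,
    methods: tuple[str, ...] = ("wilcoxon", "ttest", "moderated_t", "nb_exact"),
    replicates: int = 3,
    depth: float = 30e6,
    sd_fraction: float = 0.10,
    n_peaks: int | None = None,
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Per-file FPR and per-class recall for each method at BH < ``cutoff``."""
    design = SimulationDesign(
        depth=depth,
        sd_fraction=sd_fraction,
        replicates_per_condition=replicates,
        n_repeats=n_files,
        seed=seed,
        n_peaks=n_peaks,
    )
    specs = [MethodSpec(name) for name in methods]
    rows = []
    for i in range(n_files):
        matrix = simulate_counts(design, repeat=i)
        for row in _score_file(matrix, specs, cutoff):
            rows.append({"file": i, **row})
    return pd.DataFrame(rows)


def wilcoxon_replicate_sweep(
    seed: int,
    n_files: int = 5,
    replicate_counts: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8),
    depth: float = 30e6,
    sd_fraction: float = 0.10,
    n_peaks: int | None = None,
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Rank-sum test recall while down-sampling replicates (prefix rule)."""
    design = SimulationDesign(
        depth=depth,
        sd_fraction=sd_fraction,
        replicates_per_condition=max(replicate_counts),
        n_repeats=n_files,
        seed=seed,
        n_peaks=n_peaks,
    )
    spec = MethodSpec("wilcoxon")
    rows = []
    for i in range(n_files):
        matrix = simulate_counts(design, repeat=i)
        md = matrix.truth["mean_diff"].to_numpy()
        for k in replicate_counts:
            sub = matrix.subset_replicates(k)
            res = run_method(spec, sub)
            c = confusion(md, res.calls(cutoff))
            rows.append({"file": i, "replicates": k, "recall": recall(c), "fpr": fpr(c)})
    return pd.DataFrame(rows)


def high_noise_ttest_recall(
    seed: int,
    n_files: int = 3,
    replicates: int = 6,
    depth: float = 30e6,
    sd_fraction: float = 0.20,
    n_peaks: int | None = None,
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """t-test per-class recall under the high-noise 6-replicate design."""
    df = score_default_design(
        seed,
        n_files=n_files,
        methods=("ttest",),
        replicates=replicates,
        depth=depth,
        sd_fraction=sd_fraction,
        n_peaks=n_peaks,
        cutoff=cutoff,
    )
    return df
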