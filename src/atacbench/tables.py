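"""TSV I/O for count matrices, truth labels, design tables and results."""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import LabeledCountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_design_table",
    "write_matrix_files",
    "read_matrix_files",
    "write_result_table",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.6g"


def _check_rectangular(path) -> None:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        width = None
        for lineno, row in enumerate(reader, 1):
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(row)} fields, expected {width})"
                )


def read_count_table(path, require_int: bool = True):
    """Read a TSV count matrix (first column: peak id; header: sample ids).

    Returns (counts ndarray, peak_ids ndarray, sample ids ndarray).  Errors
    name the offending peak id or cell for duplicated ids, ragged rows and
    non-integer values in count mode.
    """
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated peak id {dup!r}")
    values = df.to_numpy()
    if require_int:
        arr = values.astype(float)
        off = np.argwhere(arr != np.rint(arr))
        if len(off):
            i, j = off[0]
            raise ValueError(
                f"{path}: non-integer count at peak {df.index[i]!r}, "
                f"sample {df.columns[j]!r}: {arr[i, j]}"
            )
        values = np.rint(arr).astype(np.int64)
    logger.info("read %d peaks x %d samples from %s", *df.shape, path)
    return values, df.index.to_numpy(), df.columns.to_numpy()


def write_count_table(path, counts, peak_ids, samples) -> None:
    pd.DataFrame(counts, index=pd.Index(peak_ids, name="peak_id"), columns=samples).to_csv(
        path, sep="\t"
    )


def read_design_table(path) -> pd.DataFrame:
    """TSV with columns sample, condition and optional batch."""
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns or "condition" not in df.columns:
        raise ValueError(f"{path}: design table needs 'sample' and 'condition' columns")
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicated sample id")
    if "batch" not in df.columns:
        df["batch"] = 0
    return df.set_index("sample")


def write_matrix_files(matrix: LabeledCountMatrix, outdir, prefix: str = "sim") -> dict:
    """Write counts/truth/design TSVs for one simulated matrix."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / f"{prefix}_counts.tsv",
        "truth": outdir / f"{prefix}_truth.tsv",
        "design": outdir / f"{prefix}_design.tsv",
    }
    write_count_table(paths["counts"], matrix.counts, matrix.peak_ids, matrix.samples)
    matrix.truth.to_csv(paths["truth"], sep="\t", float_format=FLOAT_FORMAT)
    matrix.design.to_csv(paths["design"], sep="\t")
    return {k: str(v) for k, v in paths.items()}


def read_matrix_files(counts_path, design_path, truth_path=None) -> LabeledCountMatrix:
    """Rebuild a labeled matrix from TSVs (truth optional: unlabeled data)."""
    counts, peak_ids, samples = read_count_table(counts_path)
    design = read_design_table(design_path)
    missing = [s for s in samples if s not in design.index]
    if missing:
        raise ValueError(f"samples missing from design table: {missing}")
    design = design.loc[list(samples)]
    if truth_path is not None:
        truth = pd.read_csv(truth_path, sep="\t", index_col=0)
        truth = truth.loc[list(peak_ids)]
    else:
        truth = pd.DataFrame(
            {"tier_cpm": np.nan, "mean_diff": np.nan, "direction": 0},
            index=pd.Index(peak_ids, name="peak_id"),
        )
    return LabeledCountMatrix(
        counts=counts,
        peak_ids=peak_ids,
        samples=np.asarray(samples),
        condition=design["condition"].to_numpy(),
        truth=truth,
        batch=design["batch"].to_numpy(),
    )


def write_result_table(path, result) -> None:
    result.to_frame().to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
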