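"""Bedgraph signal adjustment against batch-corrected peak counts (BeCorrect).

After batch correction of a peak-count table, genome-browser tracks still
show the uncorrected signal.  This module rescales a 4-column bedgraph so
that it is consistent with the corrected counts, using a four-regime rule
per chromosome:

1. before the first peak: the first peak's factor C_adj/C_raw,
2. after the last peak: the last peak's factor,
3. inside a peak: that peak's factor,
4. between two peaks: linear interpolation of the flanking factors in
   genomic position,

   factor(L_d) = (L_1 - L_d)/(L_1 - L_0) * C0_adj/C0_raw
               + (L_d - L_0)/(L_1 - L_0) * C1_adj/C1_raw

   with L_0 the end of the previous peak and L_1 the start of the next.

Input intervals are split at peak boundaries so each output line lies in a
single regime; between peaks the factor is evaluated at the fragment
midpoint (a ``per_base`` mode emits unit-width lines instead).  CPM tables
can be substituted for count tables; only the ratio matters.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BedgraphTrack",
    "PeakFactorTable",
    "parse_bedgraph",
    "write_bedgraph",
    "read_peak_table",
    "correction_factor",
    "correct_track",
    "correct_from_cpm",
]

_HEADER_PREFIXES = ("track", "browser", "#")


@dataclass
class BedgraphTrack:
    """Parsed bedgraph: header lines (echoed on write) plus sorted intervals."""

    intervals: pd.DataFrame  # columns: chrom, start, end, value
    headers: list[str]

    def total_mass(self, chrom: str | None = None) -> float:
        df = self.intervals
        if chrom is not None:
            df = df[df["chrom"] == chrom]
        return float(((df["end"] - df["start"]) * df["value"]).sum())


def parse_bedgraph(source) -> BedgraphTrack:
    """Parse a 4-column bedgraph (0-based half-open), keeping header lines.

    Intervals are validated (numeric, start < end, non-overlapping per
    chromosome) and sorted per chromosome; out-of-order input is sorted with
    a logged warning.  Chromosome blocks keep their order of first
    appearance.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    headers: list[str] = []
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    values: list[float] = []
    for lineno, line in enumerate(lines, 1):
        if not line.strip():
            continue
        if line.startswith(_HEADER_PREFIXES):
            headers.append(line)
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"line {lineno}: expected 4 columns, got {len(parts)}")
        chrom, s, e, v = parts
        try:
            s_i, e_i, v_f = int(s), int(e), float(v)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric coordinate or value") from exc
        if s_i >= e_i:
            raise ValueError(f"line {lineno}: start {s_i} >= end {e_i}")
        if v_f < 0:
            raise ValueError(f"line {lineno}: negative density {v_f}")
        chroms.append(chrom)
        starts.append(s_i)
        ends.append(e_i)
        values.append(v_f)
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends, "value": values})
    if len(df):
        order = list(dict.fromkeys(chroms))
        cat = pd.Categorical(df["chrom"], categories=order, ordered=True)
        sorted_df = df.assign(_c=cat.codes).sort_values(["_c", "start"], kind="stable")
        sorted_df = sorted_df.drop(columns="_c").reset_index(drop=True)
        if not sorted_df[["chrom", "start"]].equals(df[["chrom", "start"]].reset_index(drop=True)):
            logger.warning("bedgraph intervals were out of order; sorted per chromosome")
        df = sorted_df
        for chrom, grp in df.groupby("chrom", sort=False):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping bedgraph intervals on {chrom}")
    return BedgraphTrack(intervals=df, headers=headers)


def _format_value(v: float) -> str:
    return f"{v:.6g}"


def write_bedgraph(track: BedgraphTrack, path) -> None:
    with open(path, "w") as fh:
        for line in track.headers:
            fh.write(line + "\n")
        for row in track.intervals.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{_format_value(row.value)}\n")


@dataclass
class PeakFactorTable:
    """Per-chromosome sorted peaks with multiplicative correction factors."""

    by_chrom: dict[str, pd.DataFrame]  # columns: start, end, factor

    @classmethod
    def from_tables(
        cls, raw: pd.DataFrame, adjusted: pd.DataFrame, sample: str
    ) -> "PeakFactorTable":
        """Build factors C_adj/C_raw for one sample from two peak tables.

        Both tables need columns chrom/start/end plus one column per sample
        and must describe the same peaks.  Peaks with zero raw counts fall
        back to factor 1 with a logged warning.
        """
        for df, name in ((raw, "raw"), (adjusted, "adjusted")):
            if sample not in df.columns:
                raise KeyError(f"sample {sample!r} absent from {name} peak table")
        if len(raw) != len(adjusted) or not (
            raw[["chrom", "start", "end"]]
            .reset_index(drop=True)
            .equals(adjusted[["chrom", "start", "end"]].reset_index(drop=True))
        ):
            raise ValueError("raw and adjusted tables describe different peaks")
        c_raw = raw[sample].to_numpy(dtype=float)
        c_adj = adjusted[sample].to_numpy(dtype=float)
        if (c_raw < 0).any() or (c_adj < 0).any():
            raise ValueError("peak counts must be non-negative")
        factor = np.ones(len(c_raw))
        ok = c_raw > 0
        factor[ok] = c_adj[ok] / c_raw[ok]
        if (~ok).any():
            logger.warning(
                "%d peak(s) with zero raw counts; factor set to 1", int((~ok).sum())
            )
        table = raw[["chrom", "start", "end"]].copy()
        table["factor"] = factor
        by_chrom: dict[str, pd.DataFrame] = {}
        for chrom, grp in table.groupby("chrom", sort=False):
            grp = grp.sort_values("start").reset_index(drop=True)
            if (grp["start"] >= grp["end"]).any():
                raise ValueError(f"invalid peak coordinates on {chrom}")
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping peaks on {chrom}")
            by_chrom[chrom] = grp
        return cls(by_chrom=by_chrom)


def read_peak_table(path) -> pd.DataFrame:
    """TSV peak table: chrom, start, end, peak_id, then one column per sample."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "peak_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing column(s): {sorted(missing)}")
    if df["peak_id"].duplicated().any():
        dup = df.loc[df["peak_id"].duplicated(), "peak_id"].iloc[0]
        raise ValueError(f"duplicated peak id {dup!r}")
    return df


def correction_factor(position: float, peaks: pd.DataFrame) -> float:
    """Multiplicative factor at a genomic position given sorted chrom peaks.

    Implements the four regimes; continuous across regime boundaries (the
    interpolated factor at a peak edge equals that peak's factor).
    """
    starts = peaks["start"].to_numpy()
    ends = peaks["end"].to_numpy()
    factors = peaks["factor"].to_numpy()
    if position < starts[0]:
        return float(factors[0])
    if position >= ends[-1]:
        return float(factors[-1])
    i = bisect.bisect_right(starts, position) - 1
    if position < ends[i]:
        return float(factors[i])
    l0, l1 = ends[i], starts[i + 1]
    w1 = (position - l0) / (l1 - l0)
    return float((1.0 - w1) * factors[i] + w1 * factors[i + 1])


def _split_points(start: int, end: int, peaks: pd.DataFrame) -> list[int]:
    bounds = np.unique(np.concatenate([peaks["start"].to_numpy(), peaks["end"].to_numpy()]))
    inner = bounds[(bounds > start) & (bounds < end)]
    return [start, *inner.tolist(), end]


def correct_track(
    track: BedgraphTrack,
    raw: pd.DataFrame,
    adjusted: pd.DataFrame,
    sample: str,
    per_base: bool = False,
) -> BedgraphTrack:
    """Adjust every bedgraph density by the four-regime correction factor.

    Input intervals are split at peak boundaries so each output fragment
    lies wholly inside one regime; between peaks the factor is evaluated at
    the fragment midpoint (or per base when ``per_base``).  Chromosomes
    without peaks pass through unchanged.
    """
    factors = PeakFactorTable.from_tables(raw, adjusted, sample)
    out_rows: list[tuple[str, int, int, float]] = []
    for chrom, grp in track.intervals.groupby("chrom", sort=False):
        peaks = factors.by_chrom.get(chrom)
        if peaks is None:
            for row in grp.itertuples(index=False):
                out_rows.append((chrom, row.start, row.end, row.value))
            continue
        starts = peaks["start"].to_numpy()
        ends = peaks["end"].to_numpy()
        for row in grp.itertuples(index=False):
            pts = _split_points(row.start, row.end, peaks)
            for a, b in zip(pts[:-1], pts[1:]):
                mid = (a + b) / 2.0
                i = bisect.bisect_right(starts, mid) - 1
                in_gap = not (i >= 0 and mid < ends[i]) and starts[0] < mid < ends[-1]
                if per_base and in_gap:
                    for pos in range(a, b):
                        f = correction_factor(pos + 0.5, peaks)
                        out_rows.append((chrom, pos, pos + 1, row.value * f))
                else:
                    f = correction_factor(mid, peaks)
                    out_rows.append((chrom, a, b, row.value * f))
    df = pd.DataFrame(out_rows, columns=["chrom", "start", "end", "value"])
    return BedgraphTrack(intervals=df, headers=list(track.headers))


def correct_from_cpm(
    track: BedgraphTrack,
    raw_cpm: pd.DataFrame,
    adjusted_cpm: pd.DataFrame,
    sample: str,
    per_base: bool = False,
) -> BedgraphTrack:
    """As :func:`correct_track` with CPM tables; factors are CPM ratios."""
    return correct_track(track, raw_cpm, adjusted_cpm, sample, per_base=per_base)
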