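"""Adjust a bedgraph signal track to match batch-corrected peak counts.

A tiny track with two peaks: the first peak's counts double after
correction and the second's triple; densities inside each peak scale by
that ratio, the gap between them is linearly interpolated, and flanks take
the nearest peak's factor.
"""

import io

import pandas as pd

from atacbench.becorrect import correct_track, parse_bedgraph

track = parse_bedgraph(io.StringIO(
    "track type=bedGraph name=demo\n"
    "chr1\t0\t100\t2.5\n"
    "chr1\t100\t250\t1.0\n"
    "chr1\t250\t400\t3.0\n"
))
raw = pd.DataFrame({
    "chrom": "chr1", "start": [50, 300], "end": [150, 350],
    "peak_id": ["p1", "p2"], "s1": [10, 10],
})
adjusted = raw.copy()
adjusted["s1"] = [20, 30]  # factors 2x and 3x

out = correct_track(track, raw, adjusted, "s1")
print("input:")
print(track.intervals.to_string(index=False))
print("\ncorrected (split at peak boundaries):")
print(out.intervals.to_string(index=False))
mass_in = 2.5 * 50 + 1.0 * 50  # signal over peak p1 (50..150)
mass_out = sum(
    (min(r.end, 150) - max(r.start, 50)) * r.value
    for r in out.intervals.itertuples() if r.end > 50 and r.start < 150
)
print(f"\nsignal mass over p1: {mass_in:g} -> {mass_out:g} (x{mass_out / mass_in:g})")
# Signal mass over each peak scales exactly by C_adj/C_raw; between-peak
# densities get the distance-weighted mix of the two flanking factors.
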