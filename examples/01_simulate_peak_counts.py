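"""Simulate a two-condition ATAC-seq peak-count matrix with ground truth.

Builds a reduced-size version of the default design (60/30/10% of peaks at
1/5/10 CPM; 80% equal-mean peaks; 5% each at 10/20/50/100% mean difference)
and prints the composition and a few rows.
"""

import atacbench as ab

design = ab.SimulationDesign(n_peaks=10_000, replicates_per_condition=3, seed=0)
matrix = ab.simulate_counts(design)

print(f"full-design peak count would be {ab.compute_peak_count(ab.DEFAULT_TIERS):,}")
print(f"simulated {len(matrix.peak_ids):,} peaks x {len(matrix.samples)} samples")
print("library sizes (effective reads):", matrix.counts.sum(axis=0))

low, high = ab.resolve_condition_means(5.0, 0.5)
print(f"5 CPM tier at 50% difference -> condition means {low:g} and {high:g} CPM")

print("\ntier composition:")
print(matrix.truth["tier_cpm"].value_counts(normalize=True).sort_index())
print("\nclass composition:")
print(matrix.truth["mean_diff"].value_counts(normalize=True).sort_index())
print("\nfirst count rows (A1..A3 then B1..B3):")
print(matrix.counts[:5])
# Each row is one peak; truly differential peaks have condition means that
# average to the tier density with the high side (1+f) times the low side.
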