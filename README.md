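# atacbench

Benchmarking toolkit for **differential chromatin accessibility (DAR)
analysis of ATAC-seq data**. It is written for method developers and
analysts who want to measure — on data with known ground truth — how well
the common statistical strategies recover differentially accessible peaks,
how badly batch effects hurt, and how much factor-based correction helps.

The package provides five capabilities behind one importable API and a thin
`atacbench` command line:

1. **Simulator** (`atacbench.simulate`): two-condition peak-count matrices
   with tiered signal densities (60/30/10% of peaks at 1/5/10 CPM), a
   true-negative class (80% of peaks) and four true-positive classes (5%
   each at mean-difference fractions *f* = 0.10, 0.20, 0.50, 1.00). The two
   condition means of a differential peak satisfy

       (low + high) / 2 = nominal CPM,   high = low · (1 + f)

   so the 5 CPM tier at *f* = 0.5 resolves to 4 and 6 CPM. Replicate
   densities are Normal(mean, s·mean) with in-group SD fraction s ∈
   {0.10, 0.20}, converted to integer counts at a chosen effective depth
   (10/20/30 M reads under peaks). The default design has 322,581 peaks so
   the expected total density is 10⁶ CPM.
2. **Test strategies** (`atacbench.da`): Wilcoxon rank-sum (exact
   conditional null via a counting recursion for small tie-free samples),
   a two-sample t-test on log2-CPM (Welch by default, pooled on request),
   an empirical-Bayes **moderated t** (per-peak linear model, residual
   variances shrunk toward a moment-matched prior, optional batch covariate
   and mean–variance precision weights), and a **negative-binomial
   conditional exact test** with a common dispersion estimated by
   conditional maximum likelihood. All report Benjamini–Hochberg adjusted
   p-values; external tools can be benchmarked through a counts-TSV-in /
   p-value-TSV-out plug-in contract.
3. **Evaluation** (`atacbench.evaluate`): confusion counts against truth
   labels, FPR = FP/(FP+TN), recall = TP/(TP+FN), the false-discovery
   proportion FP/(FP+TP), ROC curves and AUC, and a simulate→test→evaluate
   sweep over replicate counts with repeat aggregation.
4. **Batch correction** (`atacbench.ruv`): RUVr-style removal of unwanted
   variation — factor analysis of the residuals of a per-peak linear model
   of log2-CPM on the condition design — plus PCA diagnostics.
5. **BeCorrect** (`atacbench.becorrect`): rescales bedgraph signal tracks
   to match batch-corrected peak counts with a four-regime rule (inside a
   peak: that peak's C_adj/C_raw; flanks: nearest terminal peak's factor;
   between peaks: linear interpolation of the two flanking factors in
   genomic position).

## Worked example

```sh
python examples/02_differential_tests.py
```

```
method        calls true pos false pos
wilcoxon          0        0         0
ttest           249      243         6
moderated_t    2377     2290      87
nb_exact       1756     1697      59
```

On a 20,000-peak simulation with three replicates per condition (30 M
reads, 10% in-group SD, BH < 0.05), the rank-sum test makes **zero** calls:
with 3 vs 3 samples its smallest attainable exact p-value is 0.1, which BH
can never pull below 0.05. The moderated t, which borrows variance
information across peaks, calls the most true positives; the NB exact test
sits in between; all methods keep false positives rare. The other examples
(`examples/0*.py`) walk through simulation, metric sweeps, batch-effect
injection/correction (the first unwanted factor recovers the injected
batch with |r| ≈ 1.0, and t-test recall rises from 0.50 to 0.68 after
correction) and bedgraph adjustment (signal mass over a peak scales
exactly by C_adj/C_raw).

The same operations are available from the shell:

```sh
atacbench simulate --depth 30000000 --sd 0.1 --replicates 3 --seed 1 --out run/
atacbench test --counts run/sim00_counts.tsv --design run/sim00_design.tsv \
    --method moderated_t --out run/result.tsv
atacbench evaluate --results run/result.tsv --truth run/sim00_truth.tsv \
    --out run/summary.tsv
atacbench ruv --counts run/sim00_counts.tsv --design run/sim00_design.tsv \
    --k 3 --out run/corrected.tsv
atacbench becorrect --bedgraph track.bedgraph --raw-counts raw.tsv \
    --adjusted-counts corrected.tsv --sample A1 --out track.adj.bedgraph
```

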