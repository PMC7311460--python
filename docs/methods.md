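# Methods

## The simulation model

A simulated experiment is a peaks × samples integer count matrix for two
conditions, A and B, with per-peak ground truth. Its parameters:

| parameter | default | meaning |
| --- | --- | --- |
| tiers | 60% @ 1 CPM, 30% @ 5, 10% @ 10 | nominal signal density (counts per million of effective reads) and share of peaks |
| classes | 80% @ f=0, 5% each @ f=0.1/0.2/0.5/1.0 | relative excess of the high condition over the low |
| depth | 30e6 | effective reads under peaks per sample (CPM denominator) |
| sd_fraction | 0.10 | in-group SD as a fraction of each condition's mean |
| replicates_per_condition | design-dependent | columns per condition |
| n_repeats / seed | 1 / 0 | independent files; repeat *i* uses `SeedSequence([seed, i])` |

Peak counts per tier × class cell follow the proportions exactly
(largest-remainder rounding, deterministic tie-break), never by sampling;
within each true-positive cell half the peaks are higher in A and half in
B. The two condition means of a differential peak are the unique pair with
`(low+high)/2 = nominal` and `high = low (1+f)`, i.e. `low = 2·nominal/(2+f)`.
The number of peaks, `N = round(1e6 / Σ proportion·CPM)` = 322,581 for the
default mix, makes the expected total density 10⁶ CPM so that library
sizes land on the nominal depth; `n_peaks` overrides it for desk-scale
work.

Replicate densities are `Normal(mean, sd_fraction · mean)` per condition
— noise proportional to each condition's own signal — and counts are
`round(cpm · depth / 1e6)` clamped at zero. Negative Gaussian draws are
truncated rather than redrawn: the simplest reproducible rule, with
negligible bias whenever the mean count is ≥ 10 (the worst default case,
1 CPM at 10 M depth, has mean 10 and a 0 draw probability of ~10⁻²³ at
10% SD). Down-sampling studies subset the leading replicate columns
(prefix rule) instead of re-simulating, so recall curves across replicate
counts share the same underlying draws.

`batch_inject` overlays a multiplicative batch effect on one batch of
samples: per peak, `factor = 1 + (size − 1)·g` with `g ~ Normal(1, 0.6)`
clipped at zero, so `size = 1` is exactly the identity. The heterogeneity
(spread 0.6) is chosen so that a 1.5× batch effect dominates the first
principal component of log2-CPM — the situation factor correction is for —
while CPM normalization absorbs the common part of the scaling, as it
would in real data.

### What the generator does *not* emulate

Counts are Gaussian-derived, not negative-binomially distributed, and
carry no read-level structure: no fragment lengths, no Tn5 insertion bias,
no genomic coordinates, no correlation between neighbouring peaks, and no
library-size imbalance (columns land within a fraction of a percent of the
nominal depth). Passing benchmarks here therefore demonstrate the
statistical behaviour of the tests under the stated noise model, not their
robustness to real ATAC-seq artefacts; the NB exact test in particular
sees mildly under-dispersed data relative to its own model at the 1 CPM
tier and is conservative there.

## Test strategies

All strategies consume the same matrix; rank- and t-family tests operate
on `log2((count + p_j)/(libsize_j + 2 p_j) · 1e6)` with pseudo-count
`p_j = prior_count · libsize_j / mean(libsize)` (default prior 2), the NB
test on raw counts. p-values are two-sided; BH adjustment (statsmodels) is
applied once across all peaks; fold-change is the difference of group mean
log2-CPM for every method, so methods are compared on a common scale.

**Wilcoxon rank-sum.** Exact conditional p-values from the counting
recursion `f(i,j,u) = f(i−1,j,u−j) + f(i,j−1,u)` for tie-free rows with
n₁+n₂ ≤ 25; rows with ties use the normal approximation with tie
correction and continuity correction. With 3v3 samples the smallest exact
two-sided p is 2/C(6,3) = 0.1 — the analytic reason the test cannot call
anything at BH < 0.05 with three replicates, and needs six (smallest p
2/C(12,6) ≈ 0.00216) before adjusted p-values clear the cutoff.

**Two-sample t.** Welch statistic with Satterthwaite degrees of freedom by
default; `equal_var=True` gives the pooled classic. The default matters:
under a 100% mean difference the high condition has twice the low
condition's SD, and at 3v3 the Welch penalty (df ≈ 3) is what keeps recall
near 25% where the pooled statistic would find ~84%. Since R's `t.test`
defaults to Welch, this is also what "running a t-test" means in practice
in this field. Zero-variance peaks report p = 1 when means are equal and
the smallest positive double with an infinite statistic when they differ,
keeping BH and log-scale plots finite.

**Moderated t.** Per-peak OLS (intercept + condition, plus batch dummies
when requested). Residual variances are shrunk toward a prior estimated by
moment-matching the log residual variances: with `e_g = log s²_g −
ψ(d/2) + log(d/2)`, the prior df solves `ψ′(d₀/2) = var(e) − ψ′(d/2)`
(trigamma inversion by Newton, tolerance 1e-8, ≤ 50 iterations; d₀ = ∞
when the variance of e is below ψ′(d/2)) and `s₀² = exp(mean(e) + ψ(d₀/2)
− log(d₀/2))`. The statistic uses posterior variances `(d₀s₀² + d s²)/(d₀
+ d)` on d₀ + d degrees of freedom. `prior_df=0` recovers the ordinary
pooled t exactly; `prior_df=inf` tests every peak against the common
variance. Optional precision weights come from a lowess trend of
√(residual SD) against mean log2 count, inverted at each observation's
fitted count (weight = trend⁻⁴); they default off and nothing downstream
depends on them.

**NB conditional exact test.** Assumes equal library sizes (the simulator
guarantees near-equality; unequal-size quantile adjustment is out of
scope). The common dispersion maximizes the conditional likelihood of
within-group counts given group sums; the per-peak two-sided p-value sums
the conditional probabilities of group-sum splits no more likely than the
observed one. Because that conditional distribution depends only on the
peak's total, p-values are computed once per unique total; log-pmf values
are accumulated from exact term ratios rather than large-argument
`gammaln` differences, which keeps the dispersion → 0 limit equal to the
binomial test to < 1e-6, and tied outcomes are grouped with a 1e-9
relative tolerance. A per-peak method-of-moments dispersion mode exists
for exploration. All-zero peaks report p = 1.

## Evaluation

FPR = FP/(FP+TN) over truth-labeled peaks is the headline specificity
metric; the false-discovery proportion FP/(FP+TP) is exposed separately
(`fdp`, CLI flag `--fpr-definition fdp`) because both definitions
circulate and they answer different questions. Zero-denominator cases are
reported as missing, never as zero. ROC curves sweep raw p-value
thresholds (tied p-values form a single step, so AUC is order-invariant;
curves are anchored at (0,0) and (1,1)); the BH < 0.05 operating point is
computed on adjusted values. Stratified recall uses the global BH call set
— tests run genome-wide, and per-stratum re-adjustment would answer a
different question.

## RUV correction

Residuals of per-peak OLS of log2-CPM on the condition design are
orthogonal to the design by construction; the first k left singular
vectors of the sample-side residual matrix (sign-fixed: largest-magnitude
entry positive) span the unwanted subspace. Because those factors are
orthogonal to the design, per-peak regression of log2-CPM on them reduces
to a projection, and subtracting it removes unwanted structure while
leaving the condition contrast untouched. Corrected counts invert the
log2-CPM transform at the original library sizes (round, clamp at zero) so
they drop into the test strategies and into BeCorrect. Defaults: k = 3,
column-sum library sizes (upper-quartile normalization as an option).
Residuals are least-squares on log2-CPM rather than NB deviance residuals
— deterministic, desk-scale, and adequate for multiplicative batch
effects on the log scale; a deviance-residual mode is a natural extension
point. Re-applying the correction with the same residual matrix is an
exact no-op (the projection of already-projected data is zero); re-running
the whole pipeline on corrected output would instead estimate fresh
factors from what is left and keep removing variance.

## BeCorrect

Peak tables and bedgraphs use 0-based half-open coordinates; overlapping
peaks are rejected (merged open-chromatin regions are non-overlapping by
construction), and a zero raw count yields a neutral factor 1 with a
warning rather than a division error. A bedgraph line can span several
regimes, and "the position of a density" is ambiguous for a range, so
input intervals are split at peak boundaries and the between-peak factor
is evaluated at each fragment's midpoint — one factor per output line
keeps the format valid while approximating per-base interpolation; a
`per_base` mode emits unit-width lines where exactness matters. The factor
function is continuous across regime boundaries, signal mass over each
peak scales exactly by C_adj/C_raw, and chromosomes without peaks pass
through unchanged. CPM tables may replace count tables; only ratios enter.

## Problem sizes and determinism

The acceptance script and the end-to-end tests run the full 322,581-peak
design: 5 simulated files for the 3-replicate scenarios, 5 for the
replicate down-sampling sweep and 3 for the high-noise design — enough
repeats that the across-file SD of every reported rate is well under a
percentage point, while the whole script finishes in well under a minute.
Unit and property tests use 2,000–20,000-peak reductions of the same
design. Every stochastic step derives its seed from a global seed plus the
stage name (`blake2s`, < 2³¹), so outputs are byte-stable and adding a
stage never perturbs earlier ones; TSV floats are written at 6 significant
digits.

## Known limitations

* The NB exact test's equal-library-size assumption is real: feeding it
  strongly unequal columns will bias the conditional distribution.
* The moderated-t trend weights are a simplified single-pass version of
  the usual two-pass scheme; they are off by default.
* The simulator's Gaussian counts make all methods look better-calibrated
  at low tiers than true NB data would; conclusions about *relative*
  method behaviour transfer, absolute rates need the caveat above.
* DESeq-family dispersion-shrinkage pipelines are deliberately not
  re-implemented; they can be attached through the external plug-in
  contract and benchmarked under identical truth labels.
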