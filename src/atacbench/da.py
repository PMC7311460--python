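"""Differential-accessibility test strategies on peak-count matrices.

Four native strategies are provided, mirroring the families commonly applied
to ATAC-seq count tables:

* Wilcoxon rank-sum test (exact conditional null for small tie-free samples,
  normal approximation with tie correction otherwise),
* two-sided Student's t-test with pooled variance on log2-CPM,
* empirical-Bayes moderated t-statistic: per-peak linear model with residual
  variances shrunk toward a common prior estimated by moment-matching the
  log residual variances, optional precision weights from a smoothed
  mean-variance trend and an optional batch covariate,
* negative-binomial conditional exact test with a common dispersion
  estimated by conditional maximum likelihood (equal library sizes assumed).

All strategies report a raw two-sided p-value per peak, a log2 fold-change
(difference of group mean log2-CPM), and a Benjamini-Hochberg adjusted
p-value.  External methods can be benchmarked through a file-based plug-in
contract (counts TSV in, p-value TSV out).
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import minimize_scalar
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .simulate import LabeledCountMatrix

__all__ = [
    "TestResult",
    "MethodSpec",
    "logcpm_transform",
    "wilcoxon_test",
    "student_t_test",
    "moderated_t_test",
    "nb_exact_test",
    "bh_adjust",
    "run_method",
    "METHOD_REGISTRY",
]

_TINY_P = np.nextafter(0.0, 1.0)


@dataclass
class TestResult:
    """Per-peak outcome of one differential test."""

    peak_ids: np.ndarray
    statistic: np.ndarray
    pvalue: np.ndarray
    padj: np.ndarray
    log2fc: np.ndarray
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "log2FC": self.log2fc,
                "statistic": self.statistic,
                "pvalue": self.pvalue,
                "padj": self.padj,
            },
            index=pd.Index(self.peak_ids, name="peak_id"),
        )

    def calls(self, cutoff: float = 0.05) -> np.ndarray:
        return self.padj < cutoff


@dataclass(frozen=True)
class MethodSpec:
    """Named test strategy plus options; ``external`` runs a file contract."""

    name: str
    prior_count: float = 2.0
    voom_weights: bool = False
    batch_covariate: bool = False
    dispersion_mode: str = "common"
    external_cmd: str | None = None

    def __post_init__(self) -> None:
        if self.name not in METHOD_REGISTRY and self.name != "external":
            raise ValueError(f"unknown method {self.name!r}")
        if self.name == "external" and not self.external_cmd:
            raise ValueError("external method requires external_cmd")


def logcpm_transform(
    counts: np.ndarray,
    library_sizes: np.ndarray | None = None,
    prior_count: float = 2.0,
) -> np.ndarray:
    """log2 counts-per-million with a library-size-scaled pseudo-count.

    value = log2((count + prior_j) / (libsize_j + 2 * prior_j) * 1e6) where
    prior_j = prior_count * libsize_j / mean(libsize), so zero counts map to
    a finite floor and the transform is stable across unequal depths.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = np.asarray(library_sizes, dtype=float)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be > 0")
    prior = prior_count * library_sizes / library_sizes.mean()
    return np.log2((counts + prior) / (library_sizes + 2.0 * prior) * 1e6)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _partition_cdf(n1: int, n2: int) -> np.ndarray:
    """Exact null CDF of the Mann-Whitney U statistic for tie-free samples.

    Counting recursion on which group contributes the largest observation:
    f(i, j, u) = f(i-1, j, u-j) + f(i, j-1, u), normalized by C(n1+n2, n1).
    """
    maxu = n1 * n2
    f = np.zeros((n1 + 1, n2 + 1, maxu + 1))
    f[0, :, 0] = 1.0
    f[:, 0, 0] = 1.0
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            f[i, j, :] = f[i, j - 1, :]
            f[i, j, j:] += f[i - 1, j, : maxu + 1 - j]
    pmf = f[n1, n2] / special.comb(n1 + n2, n1)
    return np.cumsum(pmf)


def _wilcoxon_exact_p(u: np.ndarray, cdf: np.ndarray) -> np.ndarray:
    """Two-sided exact p for U under the symmetric null (R-style doubling)."""
    m = len(cdf) - 1  # n1*n2
    u = np.asarray(u)
    u_round = np.rint(u).astype(int)
    lower = np.minimum(u_round, m - u_round)
    p = 2.0 * cdf[lower]
    return np.minimum(p, 1.0)


def wilcoxon_test(
    values: np.ndarray,
    groups: np.ndarray,
    peak_ids: np.ndarray | None = None,
    exact_limit: int = 25,
) -> TestResult:
    """Two-sided Wilcoxon rank-sum test per peak.

    Exact conditional p-values when n1 + n2 <= ``exact_limit`` and a row has
    no ties; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ga = groups == groups[0]
    n1, n2 = int(ga.sum()), int((~ga).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    n = n1 + n2

    ranks = stats.rankdata(values, axis=1)
    r1 = ranks[:, ga].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0

    # per-row tie structure
    srt = np.sort(values, axis=1)
    has_ties = (np.diff(srt, axis=1) == 0).any(axis=1)

    p = np.empty(values.shape[0])
    use_exact = (~has_ties) & (n <= exact_limit)
    if use_exact.any():
        cdf = _partition_cdf(n1, n2)
        p[use_exact] = _wilcoxon_exact_p(u[use_exact], cdf)
    approx = ~use_exact
    if approx.any():
        # tie-corrected variance; sum over tied groups of t^3 - t per row
        v = values[approx]
        sv = np.sort(v, axis=1)
        tie_term = np.zeros(len(sv))
        for i, row in enumerate(sv):
            _, cnt = np.unique(row, return_counts=True)
            tie_term[i] = np.sum(cnt**3 - cnt)
        sigma2 = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1.0)))
        z = u[approx] - n1 * n2 / 2.0
        cc = np.sign(z) * 0.5  # continuity correction
        with np.errstate(divide="ignore", invalid="ignore"):
            zstat = (z - cc) / np.sqrt(sigma2)
        pa = 2.0 * stats.norm.sf(np.abs(zstat))
        pa[sigma2 <= 0] = 1.0
        p[approx] = np.minimum(pa, 1.0)

    log2fc = values[:, ga].mean(axis=1) - values[:, ~ga].mean(axis=1)
    if peak_ids is None:
        peak_ids = np.arange(values.shape[0])
    return TestResult(np.asarray(peak_ids), u, p, bh_adjust(p), log2fc, "wilcoxon")


# ---------------------------------------------------------------------------
# Student's t


def student_t_test(
    values: np.ndarray,
    groups: np.ndarray,
    peak_ids: np.ndarray | None = None,
    equal_var: bool = False,
) -> TestResult:
    """Two-sided two-sample t-test per peak.

    By default the Welch statistic with Satterthwaite degrees of freedom
    (the R ``t.test`` default this benchmark family runs in practice);
    ``equal_var=True`` selects the pooled-variance classic with
    df = n1 + n2 - 2.  The two coincide when the group variances are equal.

    Degenerate zero-variance peaks report p = 1 when the group means are
    equal and the smallest representable positive p (statistic +-inf) when
    they differ, so downstream BH adjustment never sees p = 0 or NaN.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ga = groups == groups[0]
    n1, n2 = int(ga.sum()), int((~ga).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    a, b = values[:, ga], values[:, ~ga]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    diff = m1 - m2
    if equal_var:
        df = np.full(values.shape[0], n1 + n2 - 2.0)
        sp = np.sqrt((v1 * (n1 - 1) + v2 * (n2 - 1)) / (n1 + n2 - 2))
        se = sp * np.sqrt(1.0 / n1 + 1.0 / n2)
    else:
        w1, w2 = v1 / n1, v2 / n2
        se = np.sqrt(w1 + w2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (w1 + w2) ** 2 / (w1**2 / (n1 - 1) + w2**2 / (n2 - 1))
        df = np.where(np.isfinite(df), df, n1 + n2 - 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_var = se == 0
    if zero_var.any():
        equal = zero_var & (diff == 0)
        differ = zero_var & (diff != 0)
        t[equal], p[equal] = 0.0, 1.0
        t[differ] = np.sign(diff[differ]) * np.inf
        p[differ] = _TINY_P
    if peak_ids is None:
        peak_ids = np.arange(values.shape[0])
    return TestResult(np.asarray(peak_ids), t, p, bh_adjust(p), diff, "ttest")


# ---------------------------------------------------------------------------
# Moderated t (empirical-Bayes shrinkage)


def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Shrink per-peak variances toward a common prior.

    Moment-matches the distribution of log residual variances to estimate
    the prior degrees of freedom d0 and prior variance s0^2, then returns
    posterior variances (d0*s0^2 + df*s2) / (d0 + df).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) if e.size > 1 else 0.0
    resid_var = evar - special.polygamma(1, df / 2.0)
    if resid_var > 0:
        d0 = 2.0 * _trigamma_inverse(resid_var)
        s02 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0, s02 = np.inf, float(np.exp(emean))
    if np.isinf(d0):
        post = np.full_like(s2, s02)
    else:
        post = (d0 * s02 + df * s2) / (d0 + df)
    return d0, s02, post


def _voom_weights(
    counts: np.ndarray,
    design: np.ndarray,
    logcpm: np.ndarray,
    library_sizes: np.ndarray,
) -> np.ndarray:
    """Precision weights from a lowess mean-variance trend (voom-style).

    Fits sqrt(residual SD) against mean log2 count, then inverts the trend
    at each observation's fitted log2 count: weight = trend^-4.
    """
    pinv = np.linalg.pinv(design)
    beta = logcpm @ pinv.T
    fitted = beta @ design.T
    resid = logcpm - fitted
    df = counts.shape[1] - design.shape[1]
    sd = np.sqrt((resid**2).sum(axis=1) / df)
    sx = np.log2(counts + 0.5).mean(axis=1)
    sy = np.sqrt(sd)
    lo = lowess(sy, sx, frac=0.5, return_sorted=True)
    lx, ly = lo[:, 0], np.maximum(lo[:, 1], 1e-6)
    fitted_count = 2.0**fitted * (library_sizes + 1.0)[None, :] / 1e6
    obs_lx = np.log2(fitted_count + 0.5)
    trend = np.interp(obs_lx, lx, ly)
    return trend**-4.0


def moderated_t_test(
    values: np.ndarray,
    groups: np.ndarray,
    batch: np.ndarray | None = None,
    peak_ids: np.ndarray | None = None,
    prior_df: float | None = None,
    weights: np.ndarray | None = None,
) -> TestResult:
    """Empirical-Bayes moderated t-test on log2-CPM values.

    Fits a per-peak linear model (intercept + condition, plus batch dummy
    covariates when given), shrinks residual variances toward a common prior
    and tests the condition coefficient on d0 + d degrees of freedom.
    ``prior_df`` overrides the estimated d0 (0 recovers the ordinary t-test,
    inf applies complete shrinkage to the common variance).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ga = (groups == groups[0]).astype(float)
    n = values.shape[1]
    cols = [np.ones(n), ga]
    if batch is not None:
        batch = np.asarray(batch)
        for b in np.unique(batch)[1:]:
            cols.append((batch == b).astype(float))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    d = n - X.shape[1]
    if d < 1:
        raise ValueError("no residual degrees of freedom")

    if weights is None:
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = values @ (xtx_inv @ X.T).T
        resid = values - beta @ X.T
        unscaled = np.full(values.shape[0], xtx_inv[1, 1])
    else:
        w = np.asarray(weights, dtype=float)
        xtwx = np.einsum("np,gn,nq->gpq", X, w, X)
        xtwy = np.einsum("np,gn,gn->gp", X, w, values)
        beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]
        resid = values - beta @ X.T
        unscaled = np.linalg.inv(xtwx)[:, 1, 1]
    if weights is None:
        s2 = (resid**2).sum(axis=1) / d
    else:
        s2 = (weights * resid**2).sum(axis=1) / d

    if prior_df is None:
        d0, s02, s2_post = squeeze_variances(s2, d)
    elif prior_df == 0:
        d0, s02, s2_post = 0.0, float("nan"), s2
    elif np.isinf(prior_df):
        _, s02, _ = squeeze_variances(s2, d)
        d0, s2_post = np.inf, np.full_like(s2, s02)
    else:
        _, s02, _ = squeeze_variances(s2, d)
        d0 = float(prior_df)
        s2_post = (d0 * s02 + d * s2) / (d0 + d)

    se = np.sqrt(s2_post * unscaled)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[:, 1] / se
    df_total = min(d0 + d, 1e9)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    bad = ~np.isfinite(t)
    if bad.any():
        diff = beta[:, 1]
        t[bad] = np.sign(diff[bad]) * np.inf
        p[bad] = np.where(diff[bad] == 0, 1.0, _TINY_P)
        t[bad & (diff == 0)] = 0.0
    ga_mask = groups == groups[0]
    log2fc = values[:, ga_mask].mean(axis=1) - values[:, ~ga_mask].mean(axis=1)
    if peak_ids is None:
        peak_ids = np.arange(values.shape[0])
    return TestResult(np.asarray(peak_ids), t, p, bh_adjust(p), log2fc, "moderated_t")


# ---------------------------------------------------------------------------
# Negative-binomial conditional exact test


def _conditional_loglik(phi: float, counts: np.ndarray, masks: list[np.ndarray]) -> float:
    """Conditional log-likelihood of within-group counts given group sums.

    Under NB(mean mu, dispersion phi) with equal library sizes, the counts of
    a group conditional on their sum are free of mu; summing the conditional
    log-likelihood over peaks and groups gives a one-parameter criterion in
    the common dispersion phi.
    """
    r = 1.0 / phi
    ll = 0.0
    for mask in masks:
        y = counts[:, mask]
        ng = y.shape[1]
        z = y.sum(axis=1)
        ll += float(
            special.gammaln(y + r).sum()
            + len(z) * special.gammaln(ng * r)
            - special.gammaln(z + ng * r).sum()
            - len(z) * ng * special.gammaln(r)
        )
    return ll


def estimate_common_dispersion(
    counts: np.ndarray, groups: np.ndarray, bounds: tuple[float, float] = (1e-6, 5.0)
) -> float:
    """Common NB dispersion by conditional maximum likelihood."""
    counts = np.asarray(counts)
    groups = np.asarray(groups)
    masks = [groups == g for g in pd.unique(groups)]
    keep = counts.sum(axis=1) > 0
    y = counts[keep].astype(float)
    res = minimize_scalar(
        lambda lp: -_conditional_loglik(np.exp(lp), y, masks),
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.exp(res.x))


def _exact_p_for_total(total: int, n1: int, n2: int, phi: float) -> np.ndarray:
    """Two-sided exact p for every possible group-1 sum s = 0..total.

    The conditional null P(S1 = s | S1 + S2 = total) under a common NB is
    proportional to f_{NB(n1/phi)}(s) * f_{NB(n2/phi)}(total - s); the
    two-sided p-value is the total probability of outcomes no more likely
    than the observed one ("method of small p-values").
    """
    s = np.arange(total, dtype=float)
    r1, r2 = n1 / phi, n2 / phi
    # w(s) ~ Gamma(s+r1)/s! * Gamma(total-s+r2)/(total-s)!; accumulate the
    # log of the exact ratio w(s+1)/w(s) to avoid large-argument gammaln
    # cancellation in the dispersion -> 0 limit
    incr = (
        np.log(s + r1) - np.log(s + 1.0) + np.log(total - s) - np.log(total - s - 1.0 + r2)
    )
    logw = np.concatenate([[0.0], np.cumsum(incr)])
    logw -= logw.max()
    w = np.exp(logw)
    pmf = w / w.sum()
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    cum = np.cumsum(sorted_pmf)
    # p(s) = sum of pmf over outcomes with pmf <= pmf(s); the relative
    # tolerance absorbs rounding between mathematically tied outcomes
    thresh = pmf * (1.0 + 1e-9) + 1e-300
    idx = np.searchsorted(sorted_pmf, thresh, side="right") - 1
    p = cum[np.clip(idx, 0, total)]
    return np.minimum(p, 1.0)


def nb_exact_test(
    counts: np.ndarray,
    groups: np.ndarray,
    peak_ids: np.ndarray | None = None,
    dispersion_mode: str = "common",
    dispersion: float | None = None,
    prior_count: float = 2.0,
) -> TestResult:
    """Negative-binomial conditional exact test per peak.

    Assumes near-equal library sizes (as produced by the simulator): the sum
    of each group's counts is NB distributed, and the two-sided p-value is
    computed from the conditional distribution of one group's sum given the
    total.  All-zero peaks report p = 1.
    """
    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.rint(counts)):
            raise ValueError("nb_exact_test requires integer counts")
        counts = np.rint(counts).astype(np.int64)
    groups = np.asarray(groups)
    ga = groups == groups[0]
    n1, n2 = int(ga.sum()), int((~ga).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")

    if dispersion is not None:
        phi = float(dispersion)
        phi_vec = None
    elif dispersion_mode == "common":
        phi = estimate_common_dispersion(counts, groups)
        phi_vec = None
    elif dispersion_mode == "moment":
        mu = counts.mean(axis=1)
        a, b = counts[:, ga], counts[:, ~ga]
        pooled = (
            a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)
        ) / (n1 + n2 - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_vec = np.where(mu > 0, np.maximum((pooled - mu) / mu**2, 1e-6), 1e-6)
        phi = float(np.median(phi_vec))
    else:
        raise ValueError(f"unknown dispersion_mode {dispersion_mode!r}")

    s1 = counts[:, ga].sum(axis=1)
    total = counts.sum(axis=1)
    p = np.ones(counts.shape[0])
    if phi_vec is None:
        # p depends only on (total, s1); compute once per unique total
        for t in np.unique(total):
            if t == 0:
                continue
            rows = total == t
            ptab = _exact_p_for_total(int(t), n1, n2, phi)
            p[rows] = ptab[s1[rows]]
    else:
        for i in range(counts.shape[0]):
            if total[i] == 0:
                continue
            ptab = _exact_p_for_total(int(total[i]), n1, n2, float(phi_vec[i]))
            p[i] = ptab[s1[i]]

    logcpm = logcpm_transform(counts, prior_count=prior_count)
    log2fc = logcpm[:, ga].mean(axis=1) - logcpm[:, ~ga].mean(axis=1)
    if peak_ids is None:
        peak_ids = np.arange(counts.shape[0])
    return TestResult(
        np.asarray(peak_ids), s1.astype(float), p, bh_adjust(p), log2fc, "nb_exact"
    )


# ---------------------------------------------------------------------------
# Dispatch


def _run_external(cmd: str, matrix: LabeledCountMatrix) -> TestResult:
    """File contract: counts TSV in, TSV with columns peak_id/pvalue out."""
    with tempfile.TemporaryDirectory() as tmp:
        cin = Path(tmp) / "counts.tsv"
        cout = Path(tmp) / "pvalues.tsv"
        df = pd.DataFrame(
            matrix.counts, index=pd.Index(matrix.peak_ids, name="peak_id"),
            columns=matrix.samples,
        )
        df.to_csv(cin, sep="\t")
        full = cmd.format(counts=cin, out=cout)
        subprocess.run(full, shell=True, check=True)
        if not cout.exists():
            raise RuntimeError("external method produced no output file")
        res = pd.read_csv(cout, sep="\t", index_col=0)
        if "pvalue" not in res.columns:
            raise ValueError("external output must contain a 'pvalue' column")
        missing = set(matrix.peak_ids) - set(res.index.astype(str))
        if missing:
            raise ValueError(f"external output missing {len(missing)} peak(s)")
        p = res.loc[pd.Index(matrix.peak_ids), "pvalue"].to_numpy(dtype=float)
    if np.isnan(p).any() or ((p < 0) | (p > 1)).any():
        raise ValueError("external p-values malformed")
    logcpm = logcpm_transform(matrix.counts)
    ga = matrix.condition == "A"
    log2fc = logcpm[:, ga].mean(axis=1) - logcpm[:, ~ga].mean(axis=1)
    stat = res["statistic"].to_numpy(dtype=float) if "statistic" in res.columns else np.full(len(p), np.nan)
    return TestResult(matrix.peak_ids, stat, p, bh_adjust(p), log2fc, "external")


METHOD_REGISTRY = ("wilcoxon", "ttest", "moderated_t", "nb_exact", "external")


def run_method(spec: MethodSpec, matrix: LabeledCountMatrix) -> TestResult:
    """Dispatch a named strategy on a labeled count matrix.

    Count-space tests receive raw counts; rank- and t-family tests receive
    log2-CPM values from :func:`logcpm_transform`.
    """
    if spec.name == "external":
        return _run_external(spec.external_cmd, matrix)
    if spec.name == "nb_exact":
        return nb_exact_test(
            matrix.counts,
            matrix.condition,
            peak_ids=matrix.peak_ids,
            dispersion_mode=spec.dispersion_mode,
            prior_count=spec.prior_count,
        )
    values = logcpm_transform(matrix.counts, prior_count=spec.prior_count)
    if spec.name == "wilcoxon":
        return wilcoxon_test(values, matrix.condition, peak_ids=matrix.peak_ids)
    if spec.name == "ttest":
        return student_t_test(values, matrix.condition, peak_ids=matrix.peak_ids)
    if spec.name == "moderated_t":
        weights = None
        if spec.voom_weights:
            ga = (matrix.condition == matrix.condition[0]).astype(float)
            X = np.column_stack([np.ones(len(ga)), ga])
            weights = _voom_weights(
                matrix.counts.astype(float), X, values, matrix.counts.sum(axis=0).astype(float)
            )
        return moderated_t_test(
            values,
            matrix.condition,
            batch=matrix.batch if spec.batch_covariate else None,
            peak_ids=matrix.peak_ids,
            weights=weights,
        )
    raise ValueError(f"unknown method {spec.name!r}")
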