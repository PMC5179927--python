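"""Negative-binomial differential expression between two conditions.

The procedure mirrors the classic exact-test workflow for replicated count
data: median-of-ratios size factors, per-gene method-of-moments dispersion
with a parametric mean-dispersion trend alpha(mu) = a0/mu + a1 and a
maximum-sharing rule, a conditioned NB exact test per gene, BH (or
Bonferroni) adjustment, and a significance call at FDR < 0.05 and at least
1.5-fold change.

NB parameterization throughout: variance = mu + alpha * mu^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

from .counting import CountMatrix

__all__ = [
    "DISPERSION_FLOOR",
    "SizeFactors",
    "DispersionFit",
    "estimate_size_factors",
    "estimate_dispersions",
    "nbinom_exact_test",
    "adjust_pvalues",
    "call_de",
    "run_de",
    "zscore_rows",
    "hierarchical_cluster",
]

DISPERSION_FLOOR = 1e-8
# smallest reported p-value; p is never exactly 0
P_FLOOR = np.nextafter(0.0, 1.0)


@dataclass
class SizeFactors:
    """Per-sample median-of-ratios scaling factors (positive, finite)."""

    factors: pd.Series

    def __post_init__(self) -> None:
        f = self.factors.to_numpy(dtype=float)
        if not np.all(np.isfinite(f)) or not np.all(f > 0):
            raise ValueError("size factors must be positive and finite")

    def __getitem__(self, sample: str) -> float:
        return float(self.factors[sample])


@dataclass
class DispersionFit:
    """Raw, trend-fitted and final (maximum-shared) per-gene dispersions."""

    raw: pd.Series           # method-of-moments estimate, may be <= 0
    fitted: pd.Series        # from the trend alpha(mu) = a0/mu + a1
    final: pd.Series         # max(clamped raw, fitted), >= DISPERSION_FLOOR
    trend_a0: float
    trend_a1: float


def estimate_size_factors(counts: CountMatrix | pd.DataFrame) -> SizeFactors:
    """Median-of-ratios normalization with a geometric-mean pseudo-reference.

    For each sample j, factor_j is the median over genes (restricted to genes
    with a positive count in every sample, i.e. a positive geometric mean) of
    count_gj / geomean_g.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    values = mat.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has a nonzero count in every sample; median-of-ratios is "
            "undefined (consider a pseudo-reference fallback upstream)"
        )
    ref = values[all_positive]
    geomean = np.exp(np.log(ref).mean(axis=1))
    factors = np.median(ref / geomean[:, None], axis=0)
    return SizeFactors(pd.Series(factors, index=mat.columns, name="size_factor"))


def _pooled_moments(norm: np.ndarray, groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-gene overall mean and pooled within-group sample variance."""
    mean = norm.mean(axis=1)
    ss = np.zeros(norm.shape[0])
    dof = 0
    for idx in groups:
        if len(idx) >= 2:
            sub = norm[:, idx]
            ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            dof += len(idx) - 1
    return mean, ss / max(dof, 1), dof


def estimate_dispersions(
    counts: CountMatrix, size_factors: SizeFactors, min_trend_mean: float = 1.0
) -> DispersionFit:
    """Method-of-moments dispersions with a parametric trend and maximum sharing.

    The raw estimate removes the shot-noise contribution of the normalized
    counts: for k_j ~ NB(sf_j * mu, alpha), var(k_j / sf_j) = mu/sf_j +
    alpha*mu^2, so alpha_raw = (v - mu * mean(1/sf)) / mu^2 with v the pooled
    within-condition variance. The trend alpha(mu) = a0/mu + a1 is fitted by
    least squares over genes with positive raw estimates and mean >=
    ``min_trend_mean``; final = max(raw clamped at the floor, fitted).
    """
    mat = counts.counts
    sf = size_factors.factors.reindex(mat.columns).to_numpy(dtype=float)
    norm = mat.to_numpy(dtype=float) / sf
    levels = counts.conditions.unique()
    groups = [
        np.flatnonzero((counts.conditions == lvl).to_numpy()) for lvl in levels
    ]
    if max(len(g) for g in groups) < 2:
        raise ValueError(
            "dispersion estimation requires >= 2 replicates in at least one condition"
        )
    mean, var, _ = _pooled_moments(norm, groups)
    xi = float(np.mean(1.0 / sf))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mean > 0, (var - xi * mean) / mean**2, 0.0)

    usable = (raw > 0) & (mean >= min_trend_mean)
    if usable.sum() >= 2:
        x = 1.0 / mean[usable]
        y = raw[usable]
        design = np.column_stack([x, np.ones_like(x)])
        (a0, a1), *_ = np.linalg.lstsq(design, y, rcond=None)
        a0 = max(float(a0), 0.0)
        a1 = max(float(a1), 0.0)
    else:  # too few informative genes to fit a trend; fall back to the floor
        a0, a1 = 0.0, 0.0
    with np.errstate(divide="ignore"):
        fitted = np.where(mean > 0, a0 / np.maximum(mean, 1e-300) + a1, a1)
    fitted = np.maximum(fitted, DISPERSION_FLOOR)
    final = np.maximum(np.maximum(raw, DISPERSION_FLOOR), fitted)
    idx = mat.index
    return DispersionFit(
        raw=pd.Series(raw, index=idx, name="raw_dispersion"),
        fitted=pd.Series(fitted, index=idx, name="fitted_dispersion"),
        final=pd.Series(final, index=idx, name="final_dispersion"),
        trend_a0=a0,
        trend_a1=a1,
    )


def _nb_logpmf(k: np.ndarray, mean: float, var: float) -> np.ndarray:
    """log PMF of an NB (or Poisson when var ~ mean) given mean/variance.

    The Poisson branch also covers a relative variance excess below 1e-6:
    there the NB size parameter exceeds ~1e6 and gammaln cancellation costs
    more accuracy than the negligible overdispersion is worth.
    """
    if var <= mean * (1 + 1e-6):
        return sps.poisson.logpmf(k, mean)
    p = mean / var
    n = mean * mean / (var - mean)
    return sps.nbinom.logpmf(k, n, p)


def nbinom_exact_test(
    k_a: int,
    k_b: int,
    sf_a: np.ndarray,
    sf_b: np.ndarray,
    dispersion: float,
) -> float:
    """Conditioned NB exact test for one gene.

    Under the null hypothesis of equal expression, the pooled mean per unit
    size factor is mu = (k_a + k_b) / (s_a + s_b). The condition sums follow
    NB laws with mean_c = s_c * mu and variance_c = s_c * mu + alpha * mu^2 *
    sum(sf_j^2); conditioning on the total K = k_a + k_b, the p-value is the
    probability mass of all splits (a, K - a) no more likely than the
    observed one, divided by the total mass.

    A total of zero carries no information and returns p = 1 by convention.
    """
    sf_a = np.asarray(sf_a, dtype=float)
    sf_b = np.asarray(sf_b, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    total = int(k_a) + int(k_b)
    if total == 0:
        return 1.0
    s_a, s_b = sf_a.sum(), sf_b.sum()
    mu = total / (s_a + s_b)
    mean_a, mean_b = s_a * mu, s_b * mu
    var_a = mean_a + dispersion * mu * mu * np.sum(sf_a**2)
    var_b = mean_b + dispersion * mu * mu * np.sum(sf_b**2)
    ks = np.arange(total + 1)
    logp = _nb_logpmf(ks, mean_a, var_a) + _nb_logpmf(ks[::-1], mean_b, var_b)
    log_obs = logp[int(k_a)]
    # relative tolerance guards against mathematical ties lost to rounding
    # (the observed split is always included)
    keep = logp <= log_obs + 1e-8
    lse_all = _logsumexp(logp)
    p = float(np.exp(_logsumexp(logp[keep]) - lse_all))
    return min(max(p, P_FLOOR), 1.0)


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    if not np.isfinite(m):
        return -np.inf
    return float(m + np.log(np.sum(np.exp(x - m))))


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: BH step-up (default) or Bonferroni."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    raise ValueError(f"unknown adjustment method {method!r}")


def run_de(
    counts: CountMatrix,
    condition_a: str | None = None,
    condition_b: str | None = None,
    alpha: float = 0.05,
    min_fold: float = 1.5,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Full two-condition DE analysis; log2fc is condition B versus A.

    Returns a per-gene frame with normalized condition means, log2 fold
    change (pseudocount 1 added to both means when either is zero), raw and
    adjusted p-values, direction and the significance call.
    """
    levels = list(counts.conditions.unique())
    if condition_a is None or condition_b is None:
        if len(levels) != 2:
            raise ValueError(f"expected exactly 2 conditions, found {levels}")
        condition_a, condition_b = levels
    samples_a = counts.condition_samples(condition_a)
    samples_b = counts.condition_samples(condition_b)
    if not samples_a or not samples_b:
        raise ValueError("both conditions need at least one sample")

    sf = estimate_size_factors(counts)
    disp = estimate_dispersions(counts, sf)
    mat = counts.counts
    sf_a = sf.factors[samples_a].to_numpy(dtype=float)
    sf_b = sf.factors[samples_b].to_numpy(dtype=float)
    norm = mat.to_numpy(dtype=float) / sf.factors.reindex(mat.columns).to_numpy()
    ia = [mat.columns.get_loc(s) for s in samples_a]
    ib = [mat.columns.get_loc(s) for s in samples_b]
    mean_a = norm[:, ia].mean(axis=1)
    mean_b = norm[:, ib].mean(axis=1)

    ka = mat[samples_a].sum(axis=1).to_numpy()
    kb = mat[samples_b].sum(axis=1).to_numpy()
    alpha_g = disp.final.to_numpy()
    pvals = np.array(
        [
            nbinom_exact_test(ka[i], kb[i], sf_a, sf_b, alpha_g[i])
            for i in range(len(mat))
        ]
    )
    qvals = adjust_pvalues(pvals, method=adjust)

    zero = (mean_a == 0) | (mean_b == 0)
    num = np.where(zero, mean_b + 1.0, mean_b)
    den = np.where(zero, mean_a + 1.0, mean_a)
    log2fc = np.log2(num / den)

    res = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p": pvals,
            "q": qvals,
        },
        index=mat.index.rename("gene"),
    )
    return call_de(res, q_threshold=alpha, min_fold=min_fold)


def call_de(
    results: pd.DataFrame, q_threshold: float = 0.05, min_fold: float = 1.5
) -> pd.DataFrame:
    """Apply the DE call: significant iff q < threshold and |log2fc| >= log2(min_fold)."""
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    res = results.copy()
    significant = (res["q"] < q_threshold) & (
        res["log2fc"].abs() >= np.log2(min_fold)
    )
    direction = np.where(
        significant, np.where(res["log2fc"] > 0, "up", "down"), "none"
    )
    res["direction"] = direction
    res["significant"] = significant
    return res


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each row to mean 0, sample SD (ddof=1) 1; constant rows map to zeros."""
    if matrix.shape[1] < 2:
        raise ValueError("z-scoring needs >= 2 columns")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    out = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def hierarchical_cluster(matrix: pd.DataFrame) -> tuple[list[int], list[int]]:
    """Complete-linkage Euclidean clustering of rows and columns.

    Returns deterministic dendrogram leaf orderings (ties broken by index).
    """
    if matrix.size == 0:
        raise ValueError("cannot cluster an empty matrix")
    values = matrix.to_numpy(dtype=float)

    def order(data: np.ndarray) -> list[int]:
        if data.shape[0] < 2:
            return list(range(data.shape[0]))
        return [int(i) for i in leaves_list(linkage(data, method="complete", metric="euclidean"))]

    return order(values), order(values.T)
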