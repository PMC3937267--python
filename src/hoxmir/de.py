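"""Negative-binomial differential expression for count matrices.

The classic exact-test workflow for two-group RNA-seq counts:

1. remove all-zero features, add a pseudo-count of one;
2. median-of-ratios size factors, s_j = median_i k_ij / (prod_v k_iv)^(1/m),
   taken over features with all-positive counts; normalized counts
   q_ij = k_ij / s_j;
3. sample outlier rejection by PCA on normalized counts (a sample three
   or more SDs from the mean on either of the first two components,
   provided that component explains > 10% of the variance, is removed
   and size factors are re-estimated);
4. per-feature method-of-moments dispersions with a gamma-family
   alpha(mu) = a0 + a1/mu trend and a sharing-mode maximum;
5. a conditioned NB exact test on pooled per-condition counts, summing
   the joint probabilities of all splits of the observed total no more
   probable than the observed split;
6. Benjamini-Hochberg step-up correction and a signed fold change
   (case/control ratio, negative reciprocal below 1).

The NB parameterization throughout is variance = mu + alpha * mu^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import nbinom, poisson
import statsmodels.api as sm

MAX_POOLED_COUNT = 10_000_000


class NormalizationError(ValueError):
    """No feature has all-positive counts; size factors are undefined."""


# ---------------------------------------------------------------------------
# elementary operations


def add_pseudocount(matrix: pd.DataFrame, c: int = 1) -> pd.DataFrame:
    """Drop all-zero features, then add ``c`` to every remaining cell."""
    keep = matrix.sum(axis=1) > 0
    return matrix.loc[keep] + c


def estimate_size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each feature with all-positive counts the per-sample ratio to the
    feature's geometric mean is taken; the size factor is the per-sample
    median of those ratios.
    """
    k = matrix.to_numpy(dtype=float)
    all_pos = (k > 0).all(axis=1)
    if not all_pos.any():
        raise NormalizationError(
            "no feature has positive counts in every sample; "
            "size factors are undefined"
        )
    logk = np.log(k[all_pos])
    log_geomean = logk.mean(axis=1, keepdims=True)
    s = np.exp(np.median(logk - log_geomean, axis=0))
    return pd.Series(s, index=matrix.columns, name="size_factor")


def normalize(matrix: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    return matrix / size_factors


def pca_outliers(
    normalized: pd.DataFrame,
    sd_threshold: float = 3.0,
    var_fraction: float = 0.10,
    log_transform: bool = False,
) -> list[str]:
    """Flag sample outliers on the first two principal components.

    Samples are observations, features are variables (centered and
    scaled to unit variance; zero-variance features are dropped with a
    warning).  Components among the first two whose explained variance
    fraction exceeds ``var_fraction`` are retained; a sample is an
    outlier when its score is ``sd_threshold`` or more SDs away from the
    mean score on any retained component.
    """
    if normalized.shape[1] < 3:
        raise ValueError("PCA outlier detection requires >= 3 samples")
    x = normalized.to_numpy(dtype=float).T  # samples x features
    if log_transform:
        x = np.log2(x + 1)
    sd = x.std(axis=0, ddof=0)
    if (sd == 0).any():
        warnings.warn(
            f"dropping {(sd == 0).sum()} zero-variance features before PCA",
            stacklevel=2,
        )
        x = x[:, sd > 0]
        sd = sd[sd > 0]
    x = (x - x.mean(axis=0)) / sd
    u, svals, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * svals  # samples x components
    explained = svals**2 / (svals**2).sum()
    outliers: set[str] = set()
    for comp in range(min(2, scores.shape[1])):
        if explained[comp] <= var_fraction:
            continue
        sc = scores[:, comp]
        z = np.abs(sc - sc.mean())
        ssd = sc.std(ddof=0)
        if ssd == 0:
            continue
        for j in np.flatnonzero(z >= sd_threshold * ssd):
            outliers.add(normalized.columns[j])
    return [c for c in normalized.columns if c in outliers]


@dataclass
class DispersionModel:
    """Per-feature NB dispersions with a fitted 1/mu trend.

    ``final`` is the sharing-mode maximum of the raw method-of-moments
    estimate and the trend value a0 + a1/mu.
    """

    raw: pd.Series
    trend_coef: tuple[float, float]
    final: pd.Series
    base_means: pd.Series

    def trend(self, mu):
        a0, a1 = self.trend_coef
        return a0 + a1 / np.asarray(mu, dtype=float)


def estimate_dispersions(
    matrix: pd.DataFrame,
    size_factors: pd.Series,
    conditions: pd.Series,
) -> DispersionModel:
    """Method-of-moments dispersions with a gamma-fitted 1/mu trend.

    Raw per-feature dispersion: alpha_i = max(0, (w_i - z_i) / qbar_i^2)
    where w_i is the pooled within-condition sample variance of the
    normalized counts, z_i = qbar_i * mean(1/s_j) is the shot-noise term
    and qbar_i the pooled mean normalized count.  The trend
    alpha(mu) = a0 + a1/mu is fitted by a gamma-family GLM of the raw
    dispersions on 1/qbar over features with positive raw estimates, and
    each feature's final dispersion is the maximum of its raw estimate
    and the trend value.
    """
    levels = pd.unique(conditions)
    sizes = conditions.value_counts()
    if (sizes < 2).all():
        raise ValueError("need >= 2 replicates in at least one condition")
    s = size_factors.loc[matrix.columns].to_numpy(dtype=float)
    q = matrix.to_numpy(dtype=float) / s
    qbar = q.mean(axis=1)

    ss = np.zeros(matrix.shape[0])
    df = 0
    for lev in levels:
        mask = (conditions.loc[matrix.columns] == lev).to_numpy()
        n_c = int(mask.sum())
        if n_c < 2:
            continue
        qc = q[:, mask]
        ss += ((qc - qc.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += n_c - 1
    w = ss / df
    z = qbar * np.mean(1.0 / s)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(qbar > 0, np.maximum(0.0, (w - z) / qbar**2), 0.0)

    trend_coef = _fit_dispersion_trend(qbar, raw)
    a0, a1 = trend_coef
    with np.errstate(divide="ignore"):
        fitted = np.where(qbar > 0, a0 + a1 / qbar, a0)
    final = np.maximum(raw, np.maximum(fitted, 0.0))
    idx = matrix.index
    return DispersionModel(
        raw=pd.Series(raw, index=idx, name="dispersion_raw"),
        trend_coef=trend_coef,
        final=pd.Series(final, index=idx, name="dispersion"),
        base_means=pd.Series(qbar, index=idx, name="base_mean"),
    )


def _fit_dispersion_trend(qbar: np.ndarray, raw: np.ndarray) -> tuple[float, float]:
    use = (qbar > 0) & (raw > 1e-8)
    if use.sum() < 2:
        # degenerate: essentially Poisson data; flat floor at the mean raw value
        return (float(np.mean(raw[qbar > 0])) if (qbar > 0).any() else 0.0, 0.0)
    y = raw[use]
    X = np.column_stack([np.ones(use.sum()), 1.0 / qbar[use]])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(
                y, X, family=sm.families.Gamma(link=sm.families.links.Identity())
            ).fit(start_params=[np.median(y), 1.0], maxiter=200)
        a0, a1 = float(fit.params[0]), float(fit.params[1])
        if not (np.isfinite(a0) and np.isfinite(a1)):
            raise ValueError("non-finite trend fit")
    except Exception:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
    return (max(a0, 0.0), max(a1, 0.0))


def _nb_logpmf(k: np.ndarray, mu: float, var: float) -> np.ndarray:
    """log pmf of NB with given mean/variance; Poisson when var <= mu."""
    if var <= mu * (1 + 1e-8):
        return poisson.logpmf(k, mu)
    size = mu * mu / (var - mu)
    p = size / (size + mu)
    return nbinom.logpmf(k, size, p)


def nbinom_exact_test(
    matrix: pd.DataFrame,
    size_factors: pd.Series,
    dispersions: DispersionModel,
    conditions: pd.Series,
    condition_a: str | None = None,
    condition_b: str | None = None,
) -> pd.DataFrame:
    """Conditioned NB exact test of condition B versus condition A.

    Per feature, the pooled counts K_A and K_B are modeled as NB with
    means derived from the pooled normalized mean and variances from the
    feature's dispersion; the p-value sums the joint probabilities of
    every split (a, b) of K_A + K_B that is no more probable than the
    observed split, normalized by the total over all splits.  A is the
    reference (control) condition; the signed fold change is B over A.
    """
    levels = list(pd.unique(conditions))
    if condition_a is None or condition_b is None:
        if len(levels) != 2:
            raise ValueError("need exactly two conditions (or name them explicitly)")
        condition_a, condition_b = levels[0], levels[1]
    cond = conditions.loc[matrix.columns]
    mask_a = (cond == condition_a).to_numpy()
    mask_b = (cond == condition_b).to_numpy()
    if mask_a.sum() < 1 or mask_b.sum() < 1:
        raise ValueError("each condition needs >= 1 sample")

    s = size_factors.loc[matrix.columns].to_numpy(dtype=float)
    k = matrix.to_numpy(dtype=float)
    q = k / s
    qbar = q.mean(axis=1)  # pooled mean under the null
    s_a, s_b = s[mask_a], s[mask_b]
    alpha = dispersions.final.loc[matrix.index].to_numpy(dtype=float)

    rows = []
    for i, feature in enumerate(matrix.index):
        K_a = int(round(k[i, mask_a].sum()))
        K_b = int(round(k[i, mask_b].sum()))
        K = K_a + K_b
        if K > MAX_POOLED_COUNT:
            raise ValueError(
                f"{feature}: pooled count {K} exceeds the exact-test cap"
            )
        mu_a = qbar[i] * s_a.sum()
        mu_b = qbar[i] * s_b.sum()
        var_a = mu_a + alpha[i] * qbar[i] ** 2 * (s_a**2).sum()
        var_b = mu_b + alpha[i] * qbar[i] ** 2 * (s_b**2).sum()
        ks = np.arange(K + 1)
        logp = _nb_logpmf(ks, mu_a, var_a) + _nb_logpmf(ks[::-1], mu_b, var_b)
        log_obs = logp[K_a]
        keep = logp <= log_obs + 1e-7  # inclusive ties: p >= P(observed)
        pval = float(np.exp(logsumexp(logp[keep]) - logsumexp(logp)))
        pval = min(max(pval, 0.0), 1.0)
        mean_a = float(q[i, mask_a].mean())
        mean_b = float(q[i, mask_b].mean())
        rows.append(
            {
                "feature": feature,
                "mean_control": mean_a,
                "mean_case": mean_b,
                "fold_change": fold_change(mean_a, mean_b),
                "pvalue": pval,
            }
        )
    result = pd.DataFrame(rows).set_index("feature")
    result["qvalue"] = bh_adjust(result["pvalue"].to_numpy())
    return result


def bh_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` is the correction denominator and may exceed the number of
    p-values supplied (restricted-set corrections test a subset of a
    larger family).  q_(i) = min_{j>=i} m * p_(j) / j, clamped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return np.array([])
    if m is None:
        m = n
    if m < n:
        raise ValueError(f"m = {m} is smaller than the number of p-values ({n})")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(n)
    q[order] = q_sorted
    return q


def fold_change(mean_control: float, mean_case: float) -> float:
    """Signed fold change: the case/control ratio, reported as its
    negative reciprocal when below 1 (so |FC| >= 1 always)."""
    if mean_control <= 0 or mean_case <= 0:
        raise ValueError("fold change requires positive group means")
    r = mean_case / mean_control
    return r if r >= 1 else -1.0 / r


# ---------------------------------------------------------------------------
# model / results objects


class DifferentialExpression:
    """Two-group NB exact-test differential expression model.

    Parameters
    ----------
    counts : DataFrame
        Raw integer counts, features x samples.
    conditions : Series
        Condition label per sample (index = sample ids).  The first
        label in ``order`` (or first encountered) is the reference.
    """

    def __init__(self, counts: pd.DataFrame, conditions: pd.Series,
                 order: tuple[str, str] | None = None):
        if set(counts.columns) != set(conditions.index):
            raise ValueError("conditions index must match count columns")
        self.counts = counts
        self.conditions = conditions.loc[counts.columns]
        levels = list(pd.unique(self.conditions))
        if order is None:
            if len(levels) != 2:
                raise ValueError("need exactly two condition levels")
            order = (levels[0], levels[1])
        self.order = order

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, conditions, **kw):
        return cls(counts, pd.Series(conditions, index=counts.columns), **kw)

    def fit(
        self,
        pseudocount: int = 1,
        pca_filter: bool = True,
        sd_threshold: float = 3.0,
        var_fraction: float = 0.10,
        pca_log: bool = False,
    ) -> "DEResults":
        """Run the full workflow and return a results object."""
        work = add_pseudocount(self.counts, c=pseudocount)
        sf = estimate_size_factors(work)
        outliers: list[str] = []
        if pca_filter:
            outliers = pca_outliers(
                normalize(work, sf),
                sd_threshold=sd_threshold,
                var_fraction=var_fraction,
                log_transform=pca_log,
            )
            if outliers:
                work = work.drop(columns=outliers)
                sf = estimate_size_factors(work)  # re-estimate after removal
        cond = self.conditions.drop(labels=outliers)
        disp = estimate_dispersions(work, sf, cond)
        table = nbinom_exact_test(
            work, sf, disp, cond,
            condition_a=self.order[0], condition_b=self.order[1],
        )
        return DEResults(
            model=self, table=table, size_factors=sf,
            dispersion_model=disp, outliers=outliers,
        )


@dataclass
class DEResults:
    """Results of a :class:`DifferentialExpression` fit."""

    model: DifferentialExpression
    table: pd.DataFrame
    size_factors: pd.Series
    dispersion_model: DispersionModel
    outliers: list[str] = field(default_factory=list)

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["qvalue"] < fdr].sort_values("qvalue")

    def summary(self, fdr: float = 0.05) -> str:
        a, b = self.model.order
        lines = [
            "NB exact-test differential expression",
            f"  conditions: {b} vs {a} (reference)",
            f"  features tested: {len(self.table)}",
            f"  samples: {len(self.size_factors)}"
            + (f" (removed outliers: {', '.join(self.outliers)})" if self.outliers else ""),
            f"  significant at FDR {fdr}: {len(self.significant(fdr))}",
            "",
        ]
        top = self.table.sort_values("pvalue").head(10)
        lines.append(
            top.to_string(
                float_format=lambda v: f"{v:.4g}", justify="right"
            )
        )
        return "\n".join(lines)
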