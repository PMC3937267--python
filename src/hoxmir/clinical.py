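"""Negative-binomial regression of miRNA expression on clinical covariates.

Expression responses are size-factor-normalized counts rounded back to
integers and modeled with an NB GLM (log link, variance mu + alpha*mu^2,
alpha profiled by maximum likelihood).  Model building follows the
clinical-covariate workflow for neurodegenerative-disease brain series:
step-wise backward selection on Wald p-values, AIC comparison of the
inter-dependent age variables (onset age, death age, duration) while
adjusting for CAG repeat size, and the supporting univariate statistics
(Shapiro-Wilk normality, Welch's t, Pearson/Spearman correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm


def prepare_response(normalized_counts) -> np.ndarray:
    """Round normalized counts to the nearest integer, half away from zero."""
    x = np.asarray(normalized_counts, dtype=float)
    if (x < 0).any():
        raise ValueError("normalized counts must be nonnegative")
    return np.floor(x + 0.5).astype(int)


@dataclass
class GLMFit:
    """An NB regression fit: coefficients on the log scale.

    ``params``/``bse``/``pvalues`` are indexed by covariate name (plus
    ``const``); ``alpha`` is the NB dispersion (variance mu+alpha*mu^2).
    """

    response: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    alpha: float
    llf: float
    aic: float
    nobs: int
    dropped_rows: list = None

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.params.index if c != "const"]

    def summary(self) -> str:
        tab = pd.DataFrame(
            {"coef": self.params, "std err": self.bse, "P>|z|": self.pvalues}
        )
        head = (
            f"NB regression of {self.response} (n = {self.nobs}, "
            f"alpha = {self.alpha:.4g}, AIC = {self.aic:.2f})"
        )
        return head + "\n" + tab.to_string(float_format=lambda v: f"{v:.4g}")


class NBRegression:
    """Negative-binomial GLM (log link) of a count response on covariates.

    A thin model object in the statsmodels mold: construct from a
    response vector and covariate DataFrame, ``fit()`` returns a
    :class:`GLMFit`.  Rows with missing covariate or response values are
    dropped (complete-case) and recorded on the fit.
    """

    def __init__(self, response, covariates: pd.DataFrame, response_name: str = "y"):
        y = pd.Series(np.asarray(response, dtype=float), index=covariates.index)
        data = covariates.copy()
        data["__y"] = y
        complete = data.dropna()
        self.dropped_rows = [i for i in data.index if i not in complete.index]
        self.y = complete["__y"].to_numpy()
        self.X = complete.drop(columns="__y")
        self.response_name = response_name
        if len(self.y) < self.X.shape[1] + 2:
            raise ValueError(
                f"too few complete cases ({len(self.y)}) for "
                f"{self.X.shape[1]} covariates"
            )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, covariates: list[str]):
        return cls(data[response], data[covariates], response_name=response)

    @staticmethod
    def _acceptable(res) -> bool:
        if res.mle_retvals.get("converged", True):
            return True
        grad = res.mle_retvals.get("gopt")
        return grad is not None and np.max(np.abs(grad)) < 1e-3

    def fit(self, maxiter: int = 200) -> GLMFit:
        X = sm.add_constant(self.X.astype(float), has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.NegativeBinomial(self.y, X, loglike_method="nb2")
            res = model.fit(disp=False, maxiter=maxiter)
            if not self._acceptable(res):
                # optimizer sometimes stops on precision loss near the
                # optimum; polish from the current point with Nelder-Mead
                res = model.fit(
                    start_params=res.params, method="nm", disp=False,
                    maxiter=5 * maxiter,
                )
        if not self._acceptable(res):
            raise RuntimeError(
                f"NB fit for {self.response_name} did not converge: "
                f"{res.mle_retvals}"
            )
        cond = np.linalg.cond(X.to_numpy())
        if cond > 1e8:
            warnings.warn(
                f"design matrix nearly collinear (condition number {cond:.2g})",
                stacklevel=2,
            )
        names = list(X.columns)
        return GLMFit(
            response=self.response_name,
            params=res.params[names],
            bse=res.bse[names],
            pvalues=res.pvalues[names],
            alpha=float(res.params["alpha"]),
            llf=float(res.llf),
            aic=float(res.aic),
            nobs=int(res.nobs),
            dropped_rows=self.dropped_rows,
        )


def nb_glm_fit(response, covariates: pd.DataFrame, response_name: str = "y") -> GLMFit:
    """Fit an NB log-link regression; see :class:`NBRegression`."""
    return NBRegression(response, covariates, response_name=response_name).fit()


def backward_select(
    response,
    covariates: pd.DataFrame,
    alpha_stay: float = 0.05,
    response_name: str = "y",
) -> GLMFit | None:
    """Step-wise backward selection on Wald p-values.

    Iteratively refits after dropping the covariate with the largest
    Wald p-value above ``alpha_stay`` (ties broken by column order,
    later columns dropped first being equivalent to "largest p wins,
    first occurrence"), until all remaining covariates are significant.
    Returns None when every covariate is eliminated.
    """
    cols = list(covariates.columns)
    if not cols:
        raise ValueError("need >= 1 covariate")
    while cols:
        fit = nb_glm_fit(response, covariates[cols], response_name=response_name)
        pvals = fit.pvalues[cols]
        worst = pvals.idxmax()
        if pvals[worst] <= alpha_stay:
            return fit
        cols.remove(worst)
    return None


def compare_aic(
    response,
    covariates: pd.DataFrame,
    candidates: list[str],
    base: list[str] | None = None,
    response_name: str = "y",
) -> pd.DataFrame:
    """AIC ranking of base+candidate models, ascending (best first).

    Each candidate is fitted on its own complete cases; the per-model n
    is reported so unequal-n comparisons are visible.
    """
    base = list(base or [])
    rows = []
    for cand in candidates:
        fit = nb_glm_fit(
            response, covariates[base + [cand]], response_name=response_name
        )
        rows.append({"candidate": cand, "aic": fit.aic, "n": fit.nobs})
    return (
        pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# supporting univariate statistics


def normality_test(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant input")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def welch_t(a, b, tails: int = 2) -> tuple[float, float]:
    """Welch's unequal-variance t-test; one- or two-tailed p.

    The one-tailed p is for the observed direction of the difference
    (half the two-tailed p), the convention of a directional replication
    design.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("zero variance in both groups")
    t, p2 = stats.ttest_ind(a, b, equal_var=False)
    if tails == 2:
        return float(t), float(p2)
    if tails == 1:
        return float(t), float(p2 / 2)
    raise ValueError("tails must be 1 or 2")


def correlation(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation on pairwise-complete rows."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 pairwise-complete observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p)


def read_clinical_table(path) -> pd.DataFrame:
    """Clinical covariate TSV indexed by sample id."""
    return pd.read_csv(path, sep="\t", index_col="sample")
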