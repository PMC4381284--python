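"""The statistical battery of the efficacy analysis.

Logistic regression (univariable and multivariable) with odds ratios and
robust 95% confidence intervals, normality-gated two-group comparisons,
Fisher's exact and Pearson chi-square contingency tests, and an exact
one-sample proportion test.

"Robust" confidence intervals are Wald intervals built from HC1
heteroskedasticity-robust (sandwich) standard errors on the coefficient
scale and exponentiated; the classical model-based intervals are available
with ``robust=False``.  Fits use maximum likelihood (Newton/IRLS, tolerance
1e-8, at most 100 iterations); complete or quasi-complete separation is
detected — via the optimizer or via coefficients diverging past |15| — and
raised rather than silently reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

_Z975 = float(sps.norm.ppf(0.975))


class SeparationError(RuntimeError):
    """Raised when a logistic fit is separated or fails to converge."""


class RankDeficiencyError(ValueError):
    """Raised when the design matrix is not full rank."""


@dataclass(frozen=True)
class RegressionResult:
    """Per-predictor odds ratios with (robust) 95% CIs and Wald p-values."""

    predictor_names: Tuple[str, ...]
    odds_ratio: Tuple[float, ...]
    ci_low: Tuple[float, ...]
    ci_high: Tuple[float, ...]
    p_value: Tuple[float, ...]
    coef: Tuple[float, ...]
    se: Tuple[float, ...]
    n: int
    converged: bool
    robust: bool

    def __post_init__(self) -> None:
        for lo, o, hi in zip(self.ci_low, self.odds_ratio, self.ci_high):
            if not lo <= o <= hi:
                raise ValueError("CI must bracket the odds ratio")

    def as_rows(self):
        for k, name in enumerate(self.predictor_names):
            yield {
                "predictor": name,
                "odds_ratio": self.odds_ratio[k],
                "ci_low": self.ci_low[k],
                "ci_high": self.ci_high[k],
                "p_value": self.p_value[k],
            }


@dataclass(frozen=True)
class GroupComparison:
    """Two-group location comparison reported as mean +/- S.D."""

    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    test: str
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if self.test not in ("t", "mann_whitney"):
            raise ValueError(f"unknown test {self.test!r}")

    def format_mean_sd(self) -> Tuple[str, str]:
        return (
            f"{self.mean_a:.2f}±{self.sd_a:.2f}",
            f"{self.mean_b:.2f}±{self.sd_b:.2f}",
        )


def _fit_logit(y: np.ndarray, X: np.ndarray, robust: bool):
    cov_type = "HC1" if robust else "nonrobust"
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        # non-convergence is handled via the converged flag below
        warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            res = sm.Logit(y, X).fit(
                disp=0, maxiter=100, tol=1e-8, method="newton", cov_type=cov_type
            )
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(f"separation detected: {exc}") from exc
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"logistic fit failed: {exc}") from exc
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged or np.any(np.abs(res.params) > 15):
        raise SeparationError(
            "logistic fit did not converge or coefficients diverged "
            "(likely separation)"
        )
    return res


def _result_from_fit(
    res, names: Sequence[str], robust: bool, intercept: bool = True
) -> RegressionResult:
    # slice off the intercept (first column) when one was fitted
    k0 = 1 if intercept else 0
    coef = np.asarray(res.params)[k0:]
    se = np.asarray(res.bse)[k0:]
    lo = coef - _Z975 * se
    hi = coef + _Z975 * se
    z = coef / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    return RegressionResult(
        predictor_names=tuple(names),
        odds_ratio=tuple(np.exp(coef)),
        ci_low=tuple(np.exp(lo)),
        ci_high=tuple(np.exp(hi)),
        p_value=tuple(p),
        coef=tuple(coef),
        se=tuple(se),
        n=int(res.nobs),
        converged=True,
        robust=robust,
    )


def logistic_univariable(
    y: Sequence[int],
    x: Sequence[float],
    robust: bool = True,
    name: str = "x",
) -> RegressionResult:
    """ML fit of logit P(y=1) = b0 + b1*x; OR = exp(b1) with robust 95% CI."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be equal-length vectors")
    if len(y) < 10:
        raise ValueError(f"need at least 10 observations, got {len(y)}")
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValueError("y must contain both classes")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    X = sm.add_constant(x)
    res = _fit_logit(y, X, robust)
    return _result_from_fit(res, [name], robust)


def logistic_multivariable(
    y: Sequence[int],
    X: np.ndarray,
    names: Optional[Sequence[str]] = None,
    robust: bool = True,
    intercept: bool = True,
) -> RegressionResult:
    """Joint ML fit over all predictor columns of ``X`` (no intercept column).

    ``intercept=False`` drops the constant term — appropriate for
    compositional predictors (counts that partition a fixed total, e.g.
    per-element base counts of a fixed-length site), whose span already
    contains the constant and would otherwise make the design singular.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be an (n, p) matrix aligned with y")
    n, p = X.shape
    if names is None:
        names = [f"x{k+1}" for k in range(p)]
    if len(names) != p:
        raise ValueError("one name per predictor column required")
    if n <= p + 1:
        raise ValueError(f"need n > predictors + 1 (n={n}, predictors={p})")
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValueError("y must contain both classes")
    design = sm.add_constant(X, has_constant="add") if intercept else X
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        offending = _collinear_columns(X, names, with_constant=intercept)
        raise RankDeficiencyError(
            f"design matrix is rank deficient; collinear columns: {offending}"
        )
    res = _fit_logit(y, design, robust)
    return _result_from_fit(res, list(names), robust, intercept=intercept)


def _collinear_columns(X: np.ndarray, names: Sequence[str], with_constant: bool = True):
    """Greedy scan for columns exactly explained by the preceding ones."""
    offending = []
    kept = [np.ones(X.shape[0])] if with_constant else [np.zeros(X.shape[0])]
    for k in range(X.shape[1]):
        A = np.column_stack(kept)
        beta, *_ = np.linalg.lstsq(A, X[:, k], rcond=None)
        resid = X[:, k] - A @ beta
        if np.max(np.abs(resid)) < 1e-8 * max(1.0, np.max(np.abs(X[:, k]))):
            offending.append(names[k])
        else:
            kept.append(X[:, k])
    return offending


def two_group_compare(
    a: Sequence[float],
    b: Sequence[float],
    normality_rule: str = "shapiro",
    force_test: Optional[str] = None,
) -> GroupComparison:
    """Student's unpaired t-test or Mann-Whitney U, gated on normality.

    With the default rule both groups must pass Shapiro-Wilk at alpha=0.05
    for the t-test; otherwise Mann-Whitney (two-sided) is used.  An
    explicit ``force_test`` of "t" or "mann_whitney" overrides the rule.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    mean_a, sd_a = float(np.mean(a)), float(np.std(a, ddof=1))
    mean_b, sd_b = float(np.mean(b)), float(np.std(b, ddof=1))
    if sd_a == 0.0 and sd_b == 0.0 and mean_a == mean_b:
        return GroupComparison(mean_a, sd_a, mean_b, sd_b, "t", 0.0, 1.0)
    if force_test is not None:
        test = force_test
    elif normality_rule == "shapiro":
        normal = True
        for g in (a, b):
            if np.ptp(g) == 0:
                normal = False
                break
            if sps.shapiro(g).pvalue <= 0.05:
                normal = False
                break
        test = "t" if normal else "mann_whitney"
    else:
        raise ValueError(f"unknown normality rule {normality_rule!r}")
    if test == "t":
        stat, p = sps.ttest_ind(a, b, equal_var=True)
    elif test == "mann_whitney":
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(mean_a, sd_a, mean_b, sd_b, test, float(stat), float(p))


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p: hypergeometric mass of tables at most as
    probable as the observed one, at fixed margins."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a 2x2 array of non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("Fisher test on a table with a zero margin; p = 1")
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def chi_square_rxc(table: Sequence[Sequence[int]]) -> Tuple[float, float]:
    """Pearson chi-square test of homogeneity on an R x C count table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square test requires positive margins")
    stat, p, _, expected = sps.chi2_contingency(t, correction=False)
    if np.any(expected < 5):
        warnings.warn(
            "chi-square approximation doubtful: some expected counts are below 5"
        )
    return float(stat), float(p)


def one_sample_proportion(successes: int, n: int, p0: float) -> float:
    """Exact binomial two-sided p-value (minimum-likelihood method)."""
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly in (0, 1)")
    return float(sps.binomtest(successes, n, p0, alternative="two-sided").pvalue)
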