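"""Association statistics for the case-control analysis.

Welch two-sided t-tests on group score means, Pearson chi-squared tests
(no continuity correction) on 2x2 clinical contingency tables, crude odds
ratios with Woolf confidence intervals, covariate-adjusted logistic
regression (per-score-unit and per-quantile ORs), and Wald interaction
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .io import ValidationError

__all__ = [
    "TwoByTwoTable",
    "LogisticFit",
    "SeparationError",
    "welch_t_test",
    "pearson_chi2",
    "crude_or",
    "logistic_fit",
    "or_from_fit",
    "quantile_or_profile",
    "interaction_test",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class TwoByTwoTable:
    """Cell counts (a, b) = exposed row, (c, d) = unexposed row."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("negative cell count")
        if self.total == 0:
            raise ValidationError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class LogisticFit:
    coefficients: np.ndarray
    standard_errors: np.ndarray
    covariance: np.ndarray
    converged: bool
    n_iterations: int
    log_likelihood: float
    names: list


class SeparationError(RuntimeError):
    """The outcome is perfectly separated by the design; the MLE diverges."""


def welch_t_test(x, y):
    """Welch unequal-variance two-sided t-test; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each sample needs at least 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValidationError("both samples have zero variance")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pearson_chi2(table: TwoByTwoTable):
    """Pearson chi-squared on a 2x2 table, 1 df, no continuity correction.

    Equivalent to n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)). Raises if any
    marginal is zero (the statistic is undefined).
    """
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValidationError("zero marginal; chi-squared undefined")
    chi2, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return float(chi2), float(p)


def crude_or(table: TwoByTwoTable, haldane: bool = False):
    """Cross-product odds ratio ad/(bc) with a Woolf 95% CI.

    A zero cell makes the estimate degenerate; pass ``haldane=True`` to add
    0.5 to every cell (Haldane-Anscombe) instead of raising.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        if not haldane:
            raise ValidationError(
                "zero cell in 2x2 table; pass haldane=True for the "
                "Haldane-Anscombe 0.5 correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(orr) - Z95 * se), np.exp(np.log(orr) + Z95 * se)
    return float(orr), float(lo), float(hi)


def _check_design(X: np.ndarray, names):
    if X.shape[0] <= X.shape[1]:
        raise ValidationError("more design columns than observations")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(f"design matrix is rank-deficient (columns {names})")


def logistic_fit(outcome, design, add_intercept: bool = True, maxiter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald inference.

    ``design`` is a DataFrame (or 2-D array) of predictors; an intercept is
    prepended unless ``add_intercept=False``. Rank deficiency and perfect
    separation are detected and raised explicitly rather than returned as a
    silently divergent fit.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("outcome must be binary 0/1")
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["const"] + names
    _check_design(X, names)
    with np.errstate(all="ignore"):
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=maxiter, method="newton")
        except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise SeparationError(str(exc)) from exc
    fitted = res.predict()
    eps = 1e-10
    if np.all((fitted > 1 - eps) == (y == 1)) and np.all((fitted < eps) == (y == 0)) \
            and np.all((fitted > 1 - eps) | (fitted < eps)):
        raise SeparationError("outcome perfectly separated by the design")
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(
            f"logistic regression did not converge in {maxiter} iterations "
            f"(|grad| = {np.max(np.abs(model.score(res.params))):.3g})"
        )
    return LogisticFit(
        coefficients=np.asarray(res.params),
        standard_errors=np.asarray(res.bse),
        covariance=np.asarray(res.cov_params()),
        converged=True,
        n_iterations=int(res.mle_retvals.get("iterations", -1)),
        log_likelihood=float(res.llf),
        names=names,
    )


def or_from_fit(fit: LogisticFit, name: str):
    """Wald OR, 95% CI and p-value for one named coefficient."""
    i = fit.names.index(name)
    b, se = fit.coefficients[i], fit.standard_errors[i]
    z = b / se
    p = 2 * sps.norm.sf(abs(z))
    return float(np.exp(b)), float(np.exp(b - Z95 * se)), float(np.exp(b + Z95 * se)), float(p)


def quantile_or_profile(
    quantile: np.ndarray,
    case: np.ndarray,
    covariates: pd.DataFrame | None = None,
    reference_q: int = 10,
    n_quantiles: int = 20,
) -> pd.DataFrame:
    """Per-quantile odds ratios against a reference quantile.

    For each quantile q != reference, a logistic model of case status on an
    indicator of membership in q (restricted to individuals in q or the
    reference) plus the covariates is fitted; the reference quantile's OR is
    1 by definition. Quantiles with only cases or only controls are marked
    undefined rather than fitted.
    """
    quantile = np.asarray(quantile)
    case = np.asarray(case, dtype=float)
    rows = []
    ref_mask = quantile == reference_q
    if ref_mask.sum() == 0:
        raise ValidationError(f"reference quantile {reference_q} is empty")
    for q in range(1, n_quantiles + 1):
        in_q = quantile == q
        n_cases = int(case[in_q].sum())
        n_controls = int((1 - case[in_q]).sum())
        row = {"quantile": q, "n_cases": n_cases, "n_controls": n_controls,
               "or": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
               "defined": True}
        if q == reference_q:
            row.update({"or": 1.0, "ci_low": 1.0, "ci_high": 1.0, "p": np.nan})
        elif n_cases == 0 or n_controls == 0:
            row["defined"] = False
        else:
            sel = in_q | ref_mask
            X = pd.DataFrame({"in_quantile": in_q[sel].astype(float)})
            if covariates is not None:
                for c in covariates.columns:
                    X[c] = covariates[c].to_numpy()[sel]
            try:
                fit = logistic_fit(case[sel], X)
                orr, lo, hi, p = or_from_fit(fit, "in_quantile")
                row.update({"or": orr, "ci_low": lo, "ci_high": hi, "p": p})
            except (SeparationError, RuntimeError, ValidationError):
                row["defined"] = False
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["reference_quantile"] = reference_q
    return out


def interaction_test(outcome, score, modifier, covariates: pd.DataFrame | None = None):
    """Wald test of a score x binary-modifier product term.

    Fits logit(case) ~ score + modifier + score:modifier (+ covariates) and
    returns the product-term estimate and its two-sided Wald p.
    """
    modifier = np.asarray(modifier, dtype=float)
    levels = np.unique(modifier)
    if len(levels) < 2:
        raise ValidationError("modifier is constant; interaction undefined")
    if len(levels) > 2:
        raise ValidationError("modifier must be binary")
    X = pd.DataFrame(
        {
            "score": np.asarray(score, dtype=float),
            "modifier": modifier,
            "score_x_modifier": np.asarray(score, dtype=float) * modifier,
        }
    )
    if covariates is not None:
        for c in covariates.columns:
            if c in X.columns:
                raise ValidationError(f"covariate {c!r} duplicates a model term")
            X[c] = covariates[c].to_numpy()
    fit = logistic_fit(np.asarray(outcome, dtype=float), X)
    i = fit.names.index("score_x_modifier")
    b, se = fit.coefficients[i], fit.standard_errors[i]
    p = 2 * sps.norm.sf(abs(b / se))
    return float(b), float(p)
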