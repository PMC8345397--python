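"""Discrimination (ROC/AUC) and liability-scale heritability.

The discriminative value of a fitted case-control model is summarized by
the AUC in its rank (Mann-Whitney) formulation. Variance explained is
measured on the observed 0/1 scale as linear-model R^2 and transformed to
the liability scale with the prevalence- and ascertainment-corrected
formula for case-control samples:

    C   = [K(1-K)]^2 / (z^2 P(1-P))
    u   = i (P - K) / (1 - K),   theta = u (u - t)
    R2_l = C R2_o / (1 + C theta R2_o)

with K the population prevalence, P the sample case fraction,
t = Phi^-1(1-K) the liability threshold, z = phi(t), and i = z/K the mean
liability of cases. Both metrics support leave-one-covariate-out
contribution decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from .io import ValidationError
from .stats import logistic_fit

__all__ = [
    "LiabilityContext",
    "ModelComparison",
    "auc",
    "model_auc",
    "observed_r2",
    "liability_r2",
    "contribution_decomposition",
]


@dataclass(frozen=True)
class LiabilityContext:
    """Prevalence/ascertainment constants of the liability-threshold model."""

    K: float
    P: float
    t: float = field(init=False)
    z: float = field(init=False)
    i: float = field(init=False)

    def __post_init__(self):
        if not (0 < self.K < 1):
            raise ValidationError(f"prevalence K must be in (0, 1), got {self.K}")
        if not (0 < self.P < 1):
            raise ValidationError(f"case fraction P must be in (0, 1), got {self.P}")
        t = norm.ppf(1 - self.K)
        z = norm.pdf(t)
        object.__setattr__(self, "t", float(t))
        object.__setattr__(self, "z", float(z))
        object.__setattr__(self, "i", float(z / self.K))


@dataclass
class ModelComparison:
    """One leave-one-out comparison: metric with vs without a variable."""

    variable_name: str
    metric_full: float
    metric_reduced: float

    @property
    def contribution(self) -> float:
        return self.metric_full - self.metric_reduced


def auc(score, status) -> float:
    """AUC by the Mann-Whitney rank statistic; ties count 1/2.

    Equals the probability that a random case outranks a random control.
    """
    status = np.asarray(status, dtype=float)
    score = np.asarray(score, dtype=float)
    if len(np.unique(status)) < 2:
        raise ValidationError("both outcome classes must be present")
    return float(roc_auc_score(status, score))


def model_auc(outcome, design: pd.DataFrame) -> float:
    """AUC of the linear predictor of a fitted logistic model."""
    fit = logistic_fit(outcome, design)
    X = np.column_stack([np.ones(len(design)), design.to_numpy(dtype=float)])
    eta = X @ fit.coefficients
    return auc(eta, outcome)


def observed_r2(outcome, design) -> float:
    """Observed-scale R^2: linear-model R^2 of the 0/1 outcome on the design.

    For a single score this is the squared Pearson correlation between the
    score and the outcome; for a multi-column design it is OLS R^2
    (1 - SSE/SST). A constant predictor explains nothing and returns 0.
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("both outcome classes must be present")
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.all(np.ptp(X, axis=0) == 0):
        return 0.0
    X1 = np.column_stack([np.ones(len(y)), X])
    coef, _, _, _ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ coef
    sst = np.sum((y - y.mean()) ** 2)
    return float(1 - np.sum(resid**2) / sst)


def liability_r2(r2_obs: float, ctx: LiabilityContext) -> float:
    """Transform observed-scale R^2 to the liability scale.

    Uses the ascertainment-corrected case-control transformation (see module
    docstring); valid when cases are oversampled relative to the population
    prevalence. The result is clamped to [0, 1] with a warning if the
    transformation overshoots.
    """
    if not (0 <= r2_obs < 1):
        raise ValidationError(f"r2_obs must be in [0, 1), got {r2_obs}")
    K, P, t, z, i = ctx.K, ctx.P, ctx.t, ctx.z, ctx.i
    C = (K * (1 - K)) ** 2 / (z**2 * P * (1 - P))
    u = i * (P - K) / (1 - K)
    theta = u * (u - t)
    r2l = C * r2_obs / (1 + C * theta * r2_obs)
    if r2l < 0 or r2l > 1:
        warnings.warn(f"liability R^2 {r2l:.4f} clamped to [0, 1]")
        r2l = min(max(r2l, 0.0), 1.0)
    return float(r2l)


def contribution_decomposition(
    outcome,
    design: pd.DataFrame,
    metric: str = "auc",
    ctx: LiabilityContext | None = None,
    variables: list | None = None,
) -> list[ModelComparison]:
    """Leave-one-covariate-out contribution of each variable to a metric.

    For each variable the model is refitted without it; the contribution is
    metric(full) - metric(reduced). ``metric`` is "auc" or "liability_r2"
    (the latter requires a LiabilityContext).
    """
    if design.shape[1] < 2:
        raise ValidationError("decomposition needs at least 2 design columns")
    if metric not in ("auc", "liability_r2"):
        raise ValidationError(f"unknown metric {metric!r}")
    if metric == "liability_r2" and ctx is None:
        raise ValidationError("liability_r2 metric requires a LiabilityContext")

    def evaluate(cols: pd.DataFrame) -> float:
        if metric == "auc":
            return model_auc(outcome, cols)
        return liability_r2(observed_r2(outcome, cols.to_numpy(dtype=float)), ctx)

    full = evaluate(design)
    out = []
    for name in variables if variables is not None else list(design.columns):
        reduced = evaluate(design.drop(columns=[name]))
        out.append(ModelComparison(name, full, reduced))
    return out
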