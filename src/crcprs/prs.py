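"""Weighted polygenic risk score (wPRS) computation.

The score for an individual is the weighted sum of effect-allele dosages
over the included panel variants, wPRS_raw = sum_i beta_i * g_i, with two
rescaling conventions applied on top:

* **Control anchoring** — every weighted score is multiplied by the ratio of
  the control-group mean risk-allele count to the control-group mean
  weighted score, so the control mean wPRS equals the control mean
  risk-allele count. One wPRS unit is then a "risk-allele equivalent", and
  a per-unit odds ratio reads as a per-risk-allele OR.
* **Missingness rescaling** — individuals missing some variants have their
  score scaled up by the ratio of the total control-mean per-variant
  contribution to the contribution of their observed variants, which keeps
  the population mean unbiased even when weights and frequencies vary
  across variants.

The module also provides the winner's-curse conditional-MLE correction for
discovery effect sizes and equal-count quantile assignment for risk
stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .io import CohortTable, GenotypeMatrix, ValidationError, VariantPanel

__all__ = [
    "RescaleConstants",
    "winners_curse_correct",
    "correct_panel_weights",
    "raw_scores",
    "compute_rescale_constants",
    "rescale_scores",
    "assign_quantiles",
]

GENOME_WIDE_ALPHA = 5e-8  # discovery significance threshold


@dataclass
class RescaleConstants:
    """Control-group anchoring constants for the wPRS scale.

    ``anchor_ratio`` = control mean unweighted score / control mean weighted
    score. ``per_variant_control_mean`` holds each variant's mean weighted
    contribution (beta * dosage) among controls observed at that variant;
    its sum over included variants equals ``control_mean_weighted``.
    """

    control_mean_weighted: float
    control_mean_unweighted: float
    anchor_ratio: float
    per_variant_control_mean: np.ndarray
    variant_ids: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "control_mean_weighted": self.control_mean_weighted,
            "control_mean_unweighted": self.control_mean_unweighted,
            "anchor_ratio": self.anchor_ratio,
            "per_variant_control_mean": list(self.per_variant_control_mean),
            "variant_ids": list(self.variant_ids),
        }


def winners_curse_correct(beta_hat: float, se: float, alpha: float = GENOME_WIDE_ALPHA) -> float:
    """Conditional-MLE correction of a significance-selected effect size.

    A discovery estimate reported only because it crossed the two-sided
    significance threshold ``alpha`` is biased away from zero. Conditional on
    the selection event |beta_hat|/se > c with c = Phi^-1(1 - alpha/2), the
    log-likelihood of the true effect beta is

        l(beta) = log phi((beta_hat - beta)/se)
                  - log[Phi(beta/se - c) + Phi(-beta/se - c)]

    and this function returns its maximizer. The correction shrinks toward
    zero and never crosses it: 0 <= corrected/beta_hat <= 1.
    """
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if se <= 0:
        raise ValidationError(f"se must be positive, got {se}")
    if beta_hat == 0:
        return 0.0
    c = norm.ppf(1 - alpha / 2)
    sign = 1.0 if beta_hat > 0 else -1.0
    b = abs(beta_hat)

    def neg_loglik(beta):
        x = beta / se
        sel = np.logaddexp(norm.logcdf(x - c), norm.logcdf(-x - c))
        return -(norm.logpdf((b - beta) / se) - sel)

    # the maximizer lies in [0, b]: the numerator peaks at b, the selection
    # penalty is increasing in |beta|
    res = minimize_scalar(neg_loglik, bounds=(0.0, b), method="bounded",
                          options={"xatol": se * 1e-8})
    if not res.success:
        raise RuntimeError(f"winner's-curse correction failed to converge: {res.message}")
    return sign * float(res.x)


def correct_panel_weights(panel: VariantPanel, se: np.ndarray,
                          alpha: float = GENOME_WIDE_ALPHA) -> VariantPanel:
    """Apply the winner's-curse correction to every beta in a panel."""
    out = panel.copy()
    se = np.asarray(se, dtype=float)
    if se.shape != (out.n_variants,):
        raise ValidationError("se vector length must match panel size")
    betas = out.table["beta"].to_numpy()
    corrected = np.empty_like(betas)
    for i, (b, s) in enumerate(zip(betas, se)):
        try:
            corrected[i] = winners_curse_correct(b, s, alpha)
        except RuntimeError as exc:
            raise RuntimeError(
                f"winner's-curse correction failed for "
                f"{out.table['variant_id'].iloc[i]}"
            ) from exc
    out.table["beta"] = corrected
    return out


def raw_scores(geno: GenotypeMatrix, panel: VariantPanel) -> pd.DataFrame:
    """Raw weighted and unweighted scores over non-missing variants.

    Returns a score frame with columns individual_id, raw_weighted,
    raw_unweighted, n_nonmissing, complete (False for individuals with zero
    non-missing variants, who must be excluded downstream).
    """
    inc = panel.included
    if list(inc["variant_id"]) != list(geno.variant_ids):
        # allow the genotype matrix to carry extra (excluded) columns
        keep = [geno.variant_ids.index(v) for v in inc["variant_id"]]
        dosages = geno.dosages[:, keep]
    else:
        dosages = geno.dosages
    beta = inc["beta"].to_numpy()
    obs = ~np.isnan(dosages)
    d0 = np.where(obs, dosages, 0.0)
    raw_weighted = d0 @ beta
    raw_unweighted = d0.sum(axis=1)
    n_nonmissing = obs.sum(axis=1)
    scores = pd.DataFrame(
        {
            "individual_id": geno.individual_ids,
            "raw_weighted": raw_weighted,
            "raw_unweighted": raw_unweighted,
            "n_nonmissing": n_nonmissing,
            "complete": n_nonmissing > 0,
        }
    )
    return scores


def compute_rescale_constants(
    scores: pd.DataFrame,
    cohort: CohortTable,
    geno: GenotypeMatrix,
    panel: VariantPanel,
) -> RescaleConstants:
    """Anchoring constants from the control group.

    The control mean weighted (and unweighted) score is assembled per
    variant — each variant's mean contribution among controls observed at
    that variant — so the constants are well defined under missingness and
    sum exactly to the (complete-data) control means.
    """
    ctrl_ids = set(cohort.table.loc[cohort.table["group"] == "control", "individual_id"])
    mask = np.array([i in ctrl_ids for i in geno.individual_ids])
    mask &= scores["complete"].to_numpy()
    if mask.sum() == 0:
        raise ValidationError("no controls with scores; cannot anchor the wPRS scale")
    inc = panel.included
    cols = [geno.variant_ids.index(v) for v in inc["variant_id"]]
    d = geno.dosages[np.ix_(mask, cols)]
    beta = inc["beta"].to_numpy()
    with np.errstate(invalid="ignore"):
        mean_dose = np.nanmean(d, axis=0)
    if np.isnan(mean_dose).any():
        # variant unobserved in every control: its control-mean contribution
        # falls back to the panel expectation 2*eaf
        fallback = 2.0 * inc["eaf"].to_numpy()
        mean_dose = np.where(np.isnan(mean_dose), fallback, mean_dose)
    per_variant = beta * mean_dose
    cmw = float(per_variant.sum())
    cmu = float(mean_dose.sum())
    if cmw <= 0:
        raise ValidationError("control mean weighted score is not positive")
    return RescaleConstants(
        control_mean_weighted=cmw,
        control_mean_unweighted=cmu,
        anchor_ratio=cmu / cmw,
        per_variant_control_mean=per_variant,
        variant_ids=list(inc["variant_id"]),
    )


def rescale_scores(
    scores: pd.DataFrame,
    constants: RescaleConstants,
    geno: GenotypeMatrix,
    panel: VariantPanel,
) -> pd.DataFrame:
    """Final wPRS: control-anchored and missingness-rescaled.

    wprs = raw_weighted * anchor_ratio * S_all / S_obs, where S_all is the
    sum of per-variant control-mean contributions over all included variants
    and S_obs the sum over this individual's observed variants. With no
    missing variants the factor is 1 and wprs = raw_weighted * anchor_ratio
    exactly.
    """
    inc = panel.included
    cols = [geno.variant_ids.index(v) for v in inc["variant_id"]]
    obs = ~np.isnan(geno.dosages[:, cols])
    s_all = constants.per_variant_control_mean.sum()
    s_obs = obs @ constants.per_variant_control_mean
    out = scores.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(s_obs > 0, s_all / s_obs, np.nan)
    out["wprs"] = out["raw_weighted"].to_numpy() * constants.anchor_ratio * factor
    out.loc[~out["complete"], "wprs"] = np.nan
    flagged = out["complete"] & ~np.isfinite(out["wprs"])
    out.loc[flagged, "complete"] = False
    return out


def assign_quantiles(
    values: np.ndarray,
    n_quantiles: int,
    population_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Equal-count quantile bins of increasing score, 1 = lowest.

    Bin boundaries come from the masked "ranking population" only (for the
    study design: familial cases + controls); individuals outside the mask
    are placed by where their score falls between the ranked bins. Bin sizes
    within the ranking population differ by at most one, ties broken by
    stable sort order, with the larger bins first.
    """
    values = np.asarray(values, dtype=float)
    if n_quantiles < 2:
        raise ValidationError(f"n_quantiles must be >= 2, got {n_quantiles}")
    if population_mask is None:
        population_mask = np.ones(len(values), dtype=bool)
    population_mask = np.asarray(population_mask, dtype=bool) & np.isfinite(values)
    n = int(population_mask.sum())
    if n < n_quantiles:
        raise ValidationError(
            f"cannot form {n_quantiles} quantiles from {n} individuals"
        )
    idx = np.flatnonzero(population_mask)
    order = idx[np.argsort(values[idx], kind="stable")]
    base, rem = divmod(n, n_quantiles)
    sizes = np.full(n_quantiles, base)
    sizes[:rem] += 1
    bins = np.repeat(np.arange(1, n_quantiles + 1), sizes)
    out = np.zeros(len(values), dtype=int)
    out[order] = bins
    # individuals outside the ranking population: place by bin upper edges
    outside = np.flatnonzero(~population_mask & np.isfinite(values))
    if len(outside) > 0:
        edges = np.maximum.accumulate(values[order])[np.cumsum(sizes) - 1]
        out[outside] = np.clip(
            np.searchsorted(edges[:-1], values[outside], side="left") + 1,
            1,
            n_quantiles,
        )
    return out
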