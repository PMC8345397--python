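"""Published reference counts bundled for validating the statistical battery.

These are the printed cell counts from the underlying familial/early-onset
CRC case-control study: the high-vs-low wPRS clinical contingency battery
(high = wPRS quantiles 17-20, n=158; low = quantiles 1-10, n=127) with its
published chi-squared p-values and adjusted ORs, and the cohort
characteristics table used for arithmetic checks. ``run_printed_fixtures``
in the pipeline recomputes every derivable statistic from these counts and
compares against the published values.
"""

from __future__ import annotations

# Each entry: rows = (high-wPRS, low-wPRS), columns = (level1, level2);
# published chi-squared p (4 dp, no continuity correction) and the published
# adjusted OR/CI/p (covariate set not derivable from the counts).
HIGH_LOW_CONTINGENCY = {
    "gender_male_female": {
        "high": (91, 67),
        "low": (76, 51),
        "p_chi2": 0.7018,
        "or_published": (1.13, 0.70, 1.82, 0.6258),
    },
    "deceased_alive_deceased": {
        "high": (144, 13),
        "low": (116, 10),
        "p_chi2": 0.9162,
        "or_published": (0.95, 0.39, 2.30, 0.9138),
    },
    "age_dx_lt50_ge50": {
        "high": (94, 64),
        "low": (94, 33),
        "p_chi2": 0.0101,
        "or_published": (1.96, 1.18, 3.27, 0.00954),
    },
    "criteria_amsterdam_bethesda": {
        "high": (24, 134),
        "low": (17, 110),
        "p_chi2": 0.6662,
        "or_published": (0.84, 0.42, 1.65, 0.60458),
    },
    "famhx_crc_yes_no": {
        "high": (90, 64),
        "low": (53, 71),
        "p_chi2": 0.0092,
        "or_published": (1.74, 1.07, 2.84, 0.0251),
    },
    "multiple_crc_yes_no": {
        "high": (19, 139),
        "low": (6, 121),
        "p_chi2": 0.0303,
        "or_published": (2.53, 0.93, 6.85, 0.0675),
    },
    "multiple_any_yes_no": {
        "high": (28, 130),
        "low": (14, 113),
        "p_chi2": 0.1129,
        "or_published": (1.52, 0.73, 3.12, 0.2597),
    },
}

# Cohort characteristics: published per-group counts used for arithmetic
# checks (sex ratio, multiple-primary percentages) and as simulator defaults.
COHORT_CHARACTERISTICS = {
    "fcrc": {
        "n": 417, "male": 235, "female": 186,
        "ratio_male_female_published": 1.26,
        "multiple_crc": 32, "multiple_crc_pct_published": 7.67,
        "multiple_any": 53,
        "age_mean": 48.72, "age_sd": 12.40,
    },
    "sp": {
        "n": 80, "male": 53, "female": 27,
        "ratio_male_female_published": 1.96,
        "multiple_crc": 9, "multiple_crc_pct_published": 11.25,
        "age_mean": 52.29, "age_sd": 12.60,
    },
    "sporadic_crc": {
        "n": 1077, "male": 702, "female": 375,
        "ratio_male_female_published": 1.87,
        "age_mean": 66.87, "age_sd": 10.88,
    },
    # the published control ratio (1.04) is inconsistent with its own
    # printed counts: 835/807 = 1.03 at 2 dp; the count-derived value is
    # authoritative here
    "control": {
        "n": 1642, "male": 835, "female": 807,
        "ratio_male_female_published": 1.04,
        "ratio_published_inconsistent": True,
        "age_mean": 62.40, "age_sd": 10.25,
    },
}

# Published group-level wPRS summary (control-anchored scale): n, mean, SD.
GROUP_WPRS_PUBLISHED = {
    "control": (1642, 87.66, 6.37),
    "sporadic_crc": (1077, 90.66, 6.42),
    "fcrc": (417, 91.71, 6.33),
    "sp": (80, 88.71, 6.65),
}
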