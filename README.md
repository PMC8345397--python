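# crcprs

Weighted polygenic risk score (wPRS) analysis for familial/early-onset
colorectal cancer (CRC) case–control studies.

Most familial, mismatch-repair-proficient CRC patients carry no pathogenic
variant in a known high-penetrance gene. One candidate explanation is the
accumulation of common low-risk alleles. `crcprs` implements, as a tested
and reusable pipeline, the analysis design used to evaluate that
hypothesis: a GWAS-derived risk-variant weight panel is QC-filtered on
imputation quality (R² ≥ 0.3), per-individual effect-allele dosages are
combined into a weighted score, the score is rescaled onto a control-
anchored "risk-allele-equivalent" scale, and the rescaled score feeds
quantile risk stratification, covariate-adjusted association, clinical
contingency comparisons, and AUC / liability-scale heritability
decomposition. A synthetic cohort generator with the same statistical
structure (Hardy–Weinberg genotypes, logistic or liability-threshold
disease models, affected-sibling familial ascertainment, group-specific
covariates, missingness) makes every stage testable without access to
study genotypes.

It is aimed at statistical-genetics practitioners who want a transparent,
scriptable implementation of this analysis rather than a black box.

## The score and its rescaling

For individual *j* with effect-allele dosages `g_ij ∈ [0, 2]` and
per-allele log odds ratios `β_i` over the included variants:

    raw_j   = Σ_i β_i g_ij                           (weighted sum)
    wPRS_j  = raw_j · A · S_all / S_obs(j)

where `A = mean control risk-allele count / mean control weighted score`
anchors the scale so that the control mean wPRS equals the control mean
risk-allele count (one wPRS unit = one risk-allele equivalent, so a
per-unit OR reads as a per-risk-allele OR), and `S_all / S_obs(j)` rescales
individuals with missing variants by the ratio of total to observed
per-variant control-mean contributions, which keeps the population mean
unbiased under missingness.

Association is estimated by logistic regression with age and sex as
covariates; group means are compared by Welch's two-sided t-test; clinical
2×2 tables use Pearson's χ² without continuity correction; discrimination
uses the rank (Mann–Whitney) AUC; variance explained is observed-scale R²
transformed to the liability scale with the prevalence- and
ascertainment-corrected transformation. Discovery effect sizes can
optionally be shrunk for winner's curse with a selection-conditioned
maximum-likelihood estimate.

## Worked example

Simulate a study-sized cohort (417 familial cases, 1077 sporadic cases,
80 serrated-polyposis patients, 1642 controls; 95-variant panel of which 3
fail imputation QC) and run the full analysis:

```python
from crcprs.pipeline import run_pipeline

report = run_pipeline({"simulate": {"seed": 7, "n_population": 20000,
                                    "liability_h2": 0.10}})
print(report.group_stats.round(3).to_string(index=False))
```

```
       group    n  mean_wprs  sd_wprs  t_p_vs_controls  or_per_unit  or_ci_low  or_ci_high  or_p
     control 1642     94.915    6.183              NaN          NaN        NaN         NaN   NaN
sporadic_crc 1077     99.503    6.106            0.000        1.129      1.113       1.146 0.000
        fcrc  417    101.326    5.608            0.000        1.203      1.173       1.233 0.000
          sp   80     96.402    6.741            0.056        1.037      0.998       1.078 0.061
```

Familial cases score highest (mean 101.3 risk-allele equivalents vs 94.9
in controls), sporadic cases sit in between, and the serrated-polyposis
group — simulated with no genetic enrichment of its own — does not
separate from controls: the qualitative pattern the design is built to
detect. The per-unit OR column is the age/sex-adjusted odds ratio per
risk-allele equivalent. The quantile profile (familial cases + controls
split into 20 equal-count wPRS bins, OR against the 10th bin) shows the
risk gradient, e.g. for this seed:

```
 quantile  n_cases  n_controls    or  ci_low  ci_high     p
        1        1         102 0.032   0.004    0.269 0.002
       10       20          83 1.000   1.000    1.000   NaN
       20       62          40 7.050   3.375   14.724 0.000
```

and the leave-one-covariate-out decomposition attributes discrimination
and liability-scale R² to the score, age and sex:

```
      metric variable  metric_full  metric_reduced  contribution_pct
         auc     wprs        0.862           0.774             8.801
         auc      age        0.862           0.776             8.633
         auc      sex        0.862           0.862             0.042
liability_r2     wprs        0.426           0.241            18.457
liability_r2      age        0.426           0.209            21.676
liability_r2      sex        0.426           0.424             0.227
```

The same pipeline runs from files (`inputs:` block with a weight-panel
TSV, a dosage VCF with GT/DS fields, and a cohort TSV), and from the
command line:

```sh
crcprs simulate --seed 7 --outdir data/
crcprs score --panel data/panel.tsv --vcf data/dosages.vcf \
             --cohort data/cohort.tsv --out scores.tsv
crcprs analyze --config config.yaml --outdir reports/
crcprs fixtures
```

`crcprs fixtures` recomputes every statistic derivable from the bundled
published contingency counts (seven clinical χ² p-values, crude ORs,
cohort sex ratios and multiple-primary percentages) and exits non-zero on
any mismatch.

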