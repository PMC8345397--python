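# Methods

This note documents the statistical model behind `crcprs`, the choices
made where the design was genuinely open, and what the synthetic cohort
generator does and does not emulate.

## Score construction

The weighted polygenic risk score is a sum of effect-allele dosages times
per-allele log odds ratios over the panel variants that survive QC.
Imputed variants with imputation R² < 0.3 are excluded (strictly less
than: a variant at exactly 0.3 stays in); directly genotyped variants are
never excluded by this filter. Variants are keyed by chromosome, position
and unordered allele pair; rsIDs are reporting metadata only, which makes
the matching robust to identifier drift. Dosages from a VCF prefer the DS
(imputed dosage) FORMAT field over GT. Harmonization orients ALT dosages
onto the panel's effect allele (`2 − d` when the effect allele is REF);
strand-ambiguous A/T and C/G pairs are set missing under the default
`drop` policy because, without frequency-based inference, their
orientation is undecidable — the conservative convention in PRS work. All
harmonization failures degrade to missing values with a logged reason,
never to silent zeros.

### Control anchoring

The raw weighted score is multiplied by the ratio of the control-group
mean risk-allele count to the control-group mean weighted score. After
anchoring, the control mean wPRS equals the control mean risk-allele
count (≈ number of included variants when effect-allele frequencies
average one half), and one wPRS unit is interpretable as one risk-allele
equivalent. This is the only reading of "rescaled using the control mean
(unweighted/weighted) PRS" consistent with a control mean near the count
scale, and it makes per-unit ORs directly comparable across panels.

### Missingness rescaling

Individuals missing some variants have their anchored score multiplied by
`S_all / S_obs`, where `S_all` is the sum over included variants of the
per-variant control-mean weighted contribution and `S_obs` the sum over
the individual's observed variants. A bare count ratio `M/m` would bias
scores when weights and frequencies vary across variants; weighting the
correction by control-mean contributions keeps the population mean
unbiased under missing-completely-at-random dosages (verified to ~0.02%
at 10% missingness in the acceptance run). Both anchoring constants and
the per-variant contributions are computed on controls only; individuals
with zero observed variants are flagged and excluded with a logged
reason. The constants are defined per variant (mean contribution among
controls observed at that variant), so they remain well defined when
controls themselves have missing data; a variant observed in no control
falls back to its panel expectation `2·eaf·β`.

### Winner's-curse correction

Discovery effect sizes selected at genome-wide significance are biased
away from zero. The package implements the two-sided-selection
conditional MLE: with `c = Φ⁻¹(1 − α/2)` and selection event
`|β̂|/se > c`, the corrected estimate maximizes
`log φ((β̂ − β)/se) − log[Φ(β/se − c) + Φ(−β/se − c)]`, solved by bounded
scalar optimization on `[0, |β̂|]` (the maximizer cannot cross zero or
exceed the estimate). The correction is exposed as an all-or-none panel
transform and is off by default: which variants' published weights had
been shrunk is not recoverable from the study description, so the panel
weights are consumed as given unless the user opts in.

## Quantile stratification

Individuals are ranked into equal-count quantiles (default 20) of
increasing wPRS. Bin boundaries are computed on the pooled familial-case +
control population only; sporadic-CRC and serrated-polyposis individuals
are scored but placed by the resulting bin edges, not used to set them.
Bin sizes differ by at most one (larger bins first), ties broken by
stable sort order. Per-quantile ORs are estimated against the median
(10th) quantile by logistic regression restricted to the two bins with
age and sex as covariates; the reference OR is fixed at 1. The high-risk
group for clinical comparisons is quantiles 17–20, the low-risk group
quantiles 1–10; the intermediate band is reported but not compared.

## Statistical battery

* Group score comparisons use Welch's unequal-variance two-sided t-test
  on means (means with SDs are what the group summary reports).
* Clinical 2×2 tables use Pearson's χ² with one degree of freedom and
  **no** Yates continuity correction — this choice reproduces all seven
  published contingency p-values at four decimals, whereas the corrected
  statistic does not. p-values are reported to 4 decimals.
* Crude ORs are cross-products with Woolf 95% CIs; zero cells raise an
  error that suggests the optional Haldane–Anscombe 0.5 correction.
* Logistic fits are Newton-type maximum likelihood with Wald
  inference (`z = 1.96` CIs throughout). Rank-deficient designs and
  perfect separation raise explicit errors rather than returning a
  divergent fit. The clinical battery reports both crude and
  age/sex-adjusted ORs, since adjusted estimates cannot be reverse-
  engineered to a unique covariate set from published counts alone.
* Interaction tests are Wald tests on a score × binary-modifier product
  term with main effects and covariates included.

## Discrimination and heritability

AUC is the Mann–Whitney rank statistic (ties count ½), applied to the
linear predictor of the fitted logistic model. Variance explained is
linear-model R² of the 0/1 outcome on the design — the observed-scale
convention of the liability-transformation literature, not Nagelkerke —
and is transformed to the liability scale with the ascertainment-corrected
formula

    C = [K(1−K)]² / (z² P(1−P)),  u = i(P−K)/(1−K),  θ = u(u−t),
    R²_l = C·R²_o / (1 + C·θ·R²_o)

with `K` the population prevalence, `P` the sample case fraction,
`t = Φ⁻¹(1−K)`, `z = φ(t)`, `i = z/K`. The ascertainment term θ matters
here because familial cases are massively oversampled relative to
population prevalence. `K` is a configuration parameter (default 0.04,
a realistic lifetime CRC risk in a European population); the analysis
never infers it from data. In the balanced limit `K = P = 0.5` the
transform reduces to multiplication by π/2, which the tests exploit as a
closed-form oracle. Results outside [0, 1] are clamped with a warning.
Leave-one-covariate-out contributions (metric(full) − metric(without
variable)) are reported in percentage points for both AUC and R²_l.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with defaults set to the emulated study's conditions:

* **Panel**: 95 variants, MAF uniform on (0.05, 0.5) with the risk allele
  equally likely minor or major (so effect-allele frequencies average
  ~0.5 and the anchored scale sits near the count scale), per-allele
  log-ORs uniform on (0.02, 0.18) as in common CRC GWAS signals, 13
  variants flagged directly genotyped, imputation R² Beta(6, 1.5) for the
  rest with exactly 3 variants forced below the 0.3 threshold (so the QC
  filter leaves 92, as in the emulated panel). Variants are in
  Hardy–Weinberg and linkage equilibrium — the panel represents
  independent association signals, so no LD machinery is needed.
* **Disease**: either a logistic model on the centered weighted score
  with the intercept solved by root-finding so the mean case probability
  equals K, or a liability-threshold model in which the standardized
  genetic score contributes a variance share h² to a unit-normal
  liability (default h² = 0.10, matching the scale of the wPRS
  liability-R² contribution the study design reports).
* **Familial ascertainment**: each case gets one simulated full sibling
  by Mendelian transmission (each proband allele shared with probability
  ½, otherwise a fresh population draw — giving the correct sibling
  dosage correlation of ½), the sibling's status is assigned under the
  same disease model, and probands with an affected sibling form the
  familial-case pool. The familial-ascertainment demonstration in the
  acceptance battery uses h² = 0.3, chosen by a pre-implementation power
  analysis so the enrichment is reliably detectable at the simulated
  cohort size (at h² = 0.2 the one-sided test wins only ~94% of
  replicates).
* **Covariates**: group-specific truncated-normal ages and Bernoulli sex,
  family-history, multiple-primary and vital-status rates defaulting to
  the emulated cohort's characteristics table (e.g. familial cases:
  diagnosis age 48.7 ± 12.4, 56% male; controls: 62.4 ± 10.3, 51% male),
  so covariate adjustment is non-trivial.
* **Missingness**: dosages masked completely at random (default 2%).

What it does **not** emulate: linkage disequilibrium, population
structure or admixture, genotyping error, age- or sex-dependent genetic
effects, shared sibling environment, and any dependence of clinical flags
(multiple primaries, vital status) on the score. Passing tests therefore
demonstrate correctness of the pipeline's computations and calibration
under the assumed generating model, not robustness to those real-data
complications.

## Problem sizes and numerical choices

The test suite exercises study-sized cohorts (2059-individual ranking
populations) for structural checks and reduced four-group cohorts
(~500 individuals, 8000-member source populations) for end-to-end runs;
the stochastic recovery battery uses 20,000-member populations with
case-control sampling at P = 0.5 and 40,000-member populations for the
OR-coverage check (50–150 replicates per property). These sizes give the
Monte Carlo precision the assertions need while keeping a full run in the
low minutes. Logistic fits converge by Newton iterations (statsmodels
defaults, 100-iteration cap); the winner's-curse optimizer uses a bounded
golden-section/parabolic search with tolerance 10⁻⁸·se; quantile ties are
broken by stable sort; degenerate inputs (zero-variance samples, zero
marginals, empty classes, constant modifiers, rank-deficient designs)
raise typed errors at the boundary rather than propagating NaNs.

## Known limitations

* The per-variant anchoring constants assume controls are representative
  at each variant; under extreme differential missingness between groups
  the missingness correction is no longer exactly unbiased.
* The liability transformation assumes the score–liability relationship
  is linear and the liability normal; it is exact only asymptotically.
* Published adjusted ORs for the clinical battery are not exactly
  reproducible from printed counts (the covariate set behind them is not
  recoverable); only the χ² p-values are treated as exact expectations.
* The AUC decomposition refits the model without each variable; it is a
  descriptive attribution, not a variance decomposition — correlated
  covariates share credit in a way that depends on the refit.
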