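"""Synthetic cohort generator with the statistical structure the analysis assumes.

Generates every input the pipeline consumes — a risk-variant weight panel,
effect-allele dosages, and a four-group cohort phenotype table — plus a
truth record sufficient to score parameter recovery. Variants are simulated
in Hardy-Weinberg and linkage equilibrium (the panel emulates independent
GWAS association signals, so no LD machinery is needed). Disease status
follows either a logistic model on the centered weighted score or a
liability-threshold model with a configurable genetic variance share h2.
Familial cases are ascertained by simulating one sibling per case through
Mendelian transmission and retaining probands whose sibling is also
affected.

Group-specific covariate distributions default to the study cohort they
emulate: familial/early-onset CRC cases (n=417, diagnosis age 48.7 +/- 12.4,
56% male), serrated polyposis patients (n=80), hospital-based sporadic CRC
cases (n=1077, 66.9 +/- 10.9, 65% male) and screening controls (n=1642,
62.4 +/- 10.3, 51% male).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .io import CohortTable, GenotypeMatrix, ValidationError, VariantPanel

__all__ = [
    "GroupSpec",
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_panel",
    "simulate_genotypes",
    "assign_status",
    "simulate_sibling",
    "ascertain_familial",
    "apply_missingness_and_qc",
    "simulate_discovery",
    "simulate_cohort",
    "write_cohort_files",
]


@dataclass(frozen=True)
class GroupSpec:
    """Covariate model for one cohort group."""

    n: int
    age_mean: float
    age_sd: float
    age_range: tuple
    male_fraction: float
    famhx_crc_rate: float = 0.0
    famhx_unknown_rate: float = 0.0
    multiple_crc_rate: float = 0.0
    deceased_rate: float = 0.0


# Defaults mirror the cohort the pipeline emulates (sizes, age moments,
# sex ratios, family-history and multiple-primary rates per group).
DEFAULT_GROUPS = {
    "fcrc": GroupSpec(417, 48.72, 12.40, (16, 82), 0.5582,
                      famhx_crc_rate=0.5108, multiple_crc_rate=0.0767,
                      deceased_rate=0.0812),
    "sp": GroupSpec(80, 52.29, 12.60, (8, 75), 0.6625,
                    famhx_crc_rate=0.375, multiple_crc_rate=0.1125),
    "sporadic_crc": GroupSpec(1077, 66.87, 10.88, (23, 91), 0.6518,
                              famhx_crc_rate=0.1226, famhx_unknown_rate=0.1588),
    "control": GroupSpec(1642, 62.40, 10.25, (24, 92), 0.5085,
                         famhx_crc_rate=0.0512, famhx_unknown_rate=0.3337),
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults are the conditions of the emulated study: a 95-variant
    discovery panel of which 13 are directly genotyped and 3 fail the
    imputation-R^2 >= 0.3 filter (leaving 92 scored), per-allele log-OR
    magnitudes 0.02-0.18 as in common CRC GWAS hits, and a
    liability-threshold disease model at prevalence K = 0.04.
    """

    n_variants: int = 95
    maf_range: tuple = (0.05, 0.5)
    effect_model: str = "uniform"  # "uniform" | "fixed"
    per_allele_logor_range: tuple = (0.02, 0.18)
    prevalence_K: float = 0.04
    disease_model: str = "liability_threshold"  # or "logistic"
    liability_h2: float = 0.10
    n_population: int = 20_000
    case_control_sizes: tuple = (500, 1600)
    familial_rule: str = "affected_sib"  # or "none"
    missing_rate: float = 0.02
    genotyped_fraction: float = 13 / 95
    n_low_r2: int = 3
    groups: dict = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValidationError(f"bad maf_range {self.maf_range}")
        if self.per_allele_logor_range[0] > self.per_allele_logor_range[1]:
            raise ValidationError("per_allele_logor_range not ordered")
        if not (0 < self.prevalence_K < 1):
            raise ValidationError("prevalence_K must be in (0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing_rate must be in [0, 1)")
        if not (0 <= self.liability_h2 < 1):
            raise ValidationError("liability_h2 must be in [0, 1)")
        if self.seed is None:
            raise ValidationError("seed is mandatory for reproducibility")


@dataclass
class SimulatedCohort:
    """A complete synthetic study: inputs plus the generating truth."""

    panel: VariantPanel
    genotypes: GenotypeMatrix
    cohort: CohortTable
    truth: dict


_BASES = np.array(["A", "C", "G", "T"])


def simulate_panel(config: SimulationConfig, rng: np.random.Generator | None = None) -> VariantPanel:
    """Draw a risk-variant weight panel.

    Effect alleles are risk alleles by construction (beta > 0); MAFs are
    uniform on ``maf_range``; imputation R^2 has a point mass of directly
    genotyped variants, ``n_low_r2`` variants forced below the 0.3 QC
    threshold, and the remainder Beta(6, 1.5)-distributed (most mass above
    0.75, emulating a high-quality imputation run). Strand-ambiguous allele
    pairs are avoided so every simulated variant is scorable.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    m = config.n_variants
    # risk (effect) allele is the minor or the major allele with equal
    # probability, so effect-allele frequencies average ~0.5 and the
    # control-anchored score sits on the risk-allele-count scale
    maf = rng.uniform(*config.maf_range, m)
    eaf = np.where(rng.random(m) < 0.5, maf, 1 - maf)
    if config.effect_model == "fixed":
        beta = np.full(m, np.mean(config.per_allele_logor_range))
    else:
        beta = rng.uniform(*config.per_allele_logor_range, m)
    # unambiguous allele pair per variant: pick effect base, then another
    # base that is not its strand complement
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    eff = rng.choice(_BASES, m)
    oth = np.array([
        rng.choice([b for b in _BASES if b != e and b != comp[e]]) for e in eff
    ])
    genotyped = np.zeros(m, dtype=bool)
    n_geno = int(round(config.genotyped_fraction * m))
    genotyped[rng.choice(m, n_geno, replace=False)] = True
    r2 = np.full(m, np.nan)
    imputed = np.flatnonzero(~genotyped)
    r2[imputed] = rng.beta(6, 1.5, len(imputed))
    if config.n_low_r2 > 0:
        if config.n_low_r2 > len(imputed):
            raise ValidationError("n_low_r2 exceeds the number of imputed variants")
        low = rng.choice(imputed, config.n_low_r2, replace=False)
        r2[low] = rng.uniform(0.05, 0.29, config.n_low_r2)
        keep = np.setdiff1d(imputed, low)
        r2[keep] = np.clip(r2[keep], 0.31, 1.0)
    table = pd.DataFrame(
        {
            "variant_id": [f"rs{1000000 + i}" for i in range(m)],
            "chrom": [str(1 + i % 22) for i in range(m)],
            "pos": np.arange(1, m + 1) * 100_000,
            "effect_allele": eff,
            "other_allele": oth,
            "beta": beta,
            "eaf": eaf,
            "imputation_r2": r2,
            "genotyped": genotyped,
            "included": True,
        }
    )
    return VariantPanel(table)


def simulate_genotypes(panel: VariantPanel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Hardy-Weinberg dosages: per variant, Binomial(2, eaf), independent."""
    eaf = panel.table["eaf"].to_numpy()
    return rng.binomial(2, eaf, (n, len(eaf))).astype(float)


def _solve_logistic_intercept(eta: np.ndarray, K: float) -> float:
    """Intercept making the mean case probability equal K (to 1e-4)."""

    def f(a):
        return expit(a + eta).mean() - K

    lo, hi = -30.0, 10.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValidationError(f"prevalence K={K} unattainable for this effect model")
    return brentq(f, lo, hi, xtol=1e-6)


def assign_status(
    dosages: np.ndarray,
    panel: VariantPanel,
    config: SimulationConfig,
    rng: np.random.Generator,
    liabilities: np.ndarray | None = None,
):
    """Disease status under the configured model; returns (status, truth).

    Logistic: P(case) = expit(alpha + sum beta_i (g_i - 2 eaf_i)) with alpha
    solved so the mean case probability equals K. Liability threshold: the
    standardized weighted genetic score contributes variance h2 to a unit
    normal liability; case iff liability exceeds Phi^-1(1-K).
    """
    beta = panel.table["beta"].to_numpy()
    eaf = panel.table["eaf"].to_numpy()
    score = dosages @ beta
    truth = {"model": config.disease_model, "beta": beta.tolist(), "K": config.prevalence_K}
    if config.disease_model == "logistic":
        eta = score - (2 * eaf) @ beta
        alpha = _solve_logistic_intercept(eta, config.prevalence_K)
        p = expit(alpha + eta)
        status = rng.random(len(p)) < p
        truth["alpha"] = float(alpha)
    elif config.disease_model == "liability_threshold":
        h2 = config.liability_h2
        mu = (2 * eaf) @ beta
        sd = np.sqrt(((2 * eaf * (1 - eaf)) * beta**2).sum())
        gs = (score - mu) / sd
        liab = gs * np.sqrt(h2) + rng.standard_normal(len(gs)) * np.sqrt(1 - h2)
        t = norm.ppf(1 - config.prevalence_K)
        status = liab > t
        truth.update({"h2": h2, "threshold": float(t),
                      "score_mu": float(mu), "score_sd": float(sd)})
        if liabilities is not None:
            liabilities[:] = liab
    else:
        raise ValidationError(f"unknown disease_model {config.disease_model!r}")
    return status, truth


def simulate_sibling(dosages: np.ndarray, eaf: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One full sibling per row by Mendelian transmission.

    Each proband allele is shared with the sibling with probability 1/2;
    otherwise the sibling receives the parent's untransmitted allele, a
    fresh population draw at the effect-allele frequency (random mating,
    HWE). Per-variant sibling-proband dosage correlation is 1/2.
    """
    shape = dosages.shape
    a1 = np.where(dosages == 2, 1, np.where(dosages == 0, 0, rng.integers(0, 2, shape)))
    a2 = dosages - a1
    share1 = rng.random(shape) < 0.5
    share2 = rng.random(shape) < 0.5
    fresh1 = rng.random(shape) < eaf
    fresh2 = rng.random(shape) < eaf
    return (np.where(share1, a1, fresh1) + np.where(share2, a2, fresh2)).astype(float)


def ascertain_familial(
    dosages: np.ndarray,
    status: np.ndarray,
    panel: VariantPanel,
    config: SimulationConfig,
    rng: np.random.Generator,
):
    """Retain cases whose simulated sibling is also affected.

    Siblings get genotypes by Mendelian resampling and disease status under
    the same model as probands; probands with an affected sibling form the
    familial case pool. Returns (familial_mask over all rows, truth).
    """
    if config.familial_rule != "affected_sib":
        raise ValidationError("ascertain_familial requires familial_rule='affected_sib'")
    eaf = panel.table["eaf"].to_numpy()
    case_idx = np.flatnonzero(status)
    sib = simulate_sibling(dosages[case_idx], eaf, rng)
    sib_status, _ = assign_status(sib, panel, config, rng)
    familial = np.zeros(len(status), dtype=bool)
    familial[case_idx[sib_status]] = True
    truth = {
        "n_cases": int(len(case_idx)),
        "n_familial": int(familial.sum()),
        "sibling_recurrence": float(sib_status.mean()) if len(case_idx) else np.nan,
    }
    return familial, truth


def apply_missingness_and_qc(
    dosages: np.ndarray,
    panel: VariantPanel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mask dosages missing completely at random at ``missing_rate``.

    The panel's imputation R^2 values (attached at panel simulation) carry
    the QC side; this step only injects missingness into the dosages.
    """
    if config.missing_rate == 0:
        return dosages
    out = dosages.copy()
    out[rng.random(dosages.shape) < config.missing_rate] = np.nan
    return out


def simulate_discovery(beta_true, se, alpha: float = 5e-8,
                       rng: np.random.Generator | None = None, size: int | None = None):
    """Discovery-GWAS replicate: beta_hat ~ N(beta_true, se^2) and the
    genome-wide significance selection event |beta_hat|/se > Phi^-1(1-alpha/2).

    Returns (beta_hat, selected)."""
    if np.any(np.asarray(se) <= 0):
        raise ValidationError("se must be positive")
    rng = np.random.default_rng(0) if rng is None else rng
    beta_true = np.asarray(beta_true, dtype=float)
    shape = beta_true.shape if size is None else (size,) + beta_true.shape
    beta_hat = rng.normal(beta_true, se, shape)
    c = norm.ppf(1 - alpha / 2)
    selected = np.abs(beta_hat) / se > c
    return beta_hat, selected


def _truncnorm(rng, mean, sd, lo, hi, n):
    x = rng.normal(mean, sd, n)
    bad = (x < lo) | (x > hi)
    while bad.any():
        x[bad] = rng.normal(mean, sd, bad.sum())
        bad = (x < lo) | (x > hi)
    return x


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Full four-group study: controls, sporadic cases, familial cases, SP.

    Draws population batches under the disease model until the group quotas
    are filled: controls and sporadic cases are unaffected/affected
    population members; familial cases additionally require an affected
    simulated sibling (when the affected-sib rule is on); serrated polyposis
    patients are drawn from the case and control pools in the study's
    affected ratio, carrying no PRS enrichment of their own beyond their CRC
    status. Covariates (age, sex, family history, multiple primaries, vital
    status, diagnostic criteria) follow the per-group models in ``groups``.
    """
    rng = np.random.default_rng(config.seed)
    panel = simulate_panel(config, rng)
    g = config.groups
    need_sp_cases = int(round(g["sp"].n * 0.4125))
    need_sp_ctrl = g["sp"].n - need_sp_cases
    need = {
        "control": g["control"].n + need_sp_ctrl,
        "sporadic_crc": g["sporadic_crc"].n + need_sp_cases,
        "fcrc": g["fcrc"].n,
    }
    pools: dict[str, list] = {k: [] for k in need}
    guard = 0
    while any(len(pools[k]) < need[k] for k in need) and guard < 200:
        guard += 1
        batch = simulate_genotypes(panel, config.n_population, rng)
        status, truth_model = assign_status(batch, panel, config, rng)
        if config.familial_rule == "affected_sib":
            familial, _ = ascertain_familial(batch, status, panel, config, rng)
        else:
            familial = status & (rng.random(len(status)) < g["fcrc"].famhx_crc_rate)
        take = {
            "control": np.flatnonzero(~status),
            "sporadic_crc": np.flatnonzero(status & ~familial),
            "fcrc": np.flatnonzero(familial),
        }
        for k, idx in take.items():
            short = need[k] - len(pools[k])
            if short > 0:
                pools[k].extend(batch[idx[:short]])
    for k in need:
        if len(pools[k]) < need[k]:
            raise ValidationError(
                f"could not fill group {k!r}: got {len(pools[k])}/{need[k]}; "
                "raise n_population or relax the design"
            )
    rows, labels = [], []
    for k in ("control", "sporadic_crc", "fcrc"):
        rows.extend(pools[k][: g[k].n])
        labels.extend([k] * g[k].n)
    # SP draws: the extra case/control pool members reserved above
    rows.extend(pools["sporadic_crc"][g["sporadic_crc"].n:])
    rows.extend(pools["control"][g["control"].n:])
    labels.extend(["sp"] * (need_sp_cases + need_sp_ctrl))
    sp_affected = [True] * need_sp_cases + [False] * need_sp_ctrl
    dosages = np.vstack(rows)
    dosages = apply_missingness_and_qc(dosages, panel, config, rng)
    n_total = len(labels)
    ids = [f"I{i:05d}" for i in range(n_total)]
    geno = GenotypeMatrix(ids, list(panel.table["variant_id"]), dosages)

    rec = []
    sp_iter = iter(sp_affected)
    for iid, grp in zip(ids, labels):
        spec = g[grp]
        affected = grp in ("fcrc", "sporadic_crc") or (grp == "sp" and next(sp_iter))
        age = float(_truncnorm(rng, spec.age_mean, spec.age_sd, *spec.age_range, 1)[0])
        famhx_u = rng.random() < spec.famhx_unknown_rate
        famhx = "unknown" if famhx_u else (
            "yes" if rng.random() < spec.famhx_crc_rate / max(1 - spec.famhx_unknown_rate, 1e-9)
            else "no"
        )
        if grp == "fcrc" and config.familial_rule == "affected_sib":
            famhx = "yes" if rng.random() < 0.95 else "no"  # sibling known affected; rare missing report
        criteria = "none"
        if grp == "fcrc":
            criteria = "amsterdam" if rng.random() < 0.1343 else "bethesda"
        elif grp == "sp":
            criteria = "who_I" if rng.random() < 0.40 else "who_II"
        rec.append(
            {
                "individual_id": iid,
                "group": grp,
                "crc_affected": bool(affected) if grp != "sp" else bool(affected),
                "sex": "male" if rng.random() < spec.male_fraction else "female",
                "age": age,
                "age_at_dx": age if (affected or grp == "sp") else "",
                "fam_history_crc": famhx,
                "fam_history_any": famhx,
                "multiple_crc": bool(rng.random() < spec.multiple_crc_rate),
                "multiple_any": bool(rng.random() < spec.multiple_crc_rate * 1.6),
                "criteria": criteria,
                "deceased": "deceased" if rng.random() < spec.deceased_rate else "alive",
            }
        )
    cohort = CohortTable(pd.DataFrame(rec))
    truth = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
            if k != "groups"
        },
        "disease": truth_model,
        "group_sizes": cohort.group_counts(),
    }
    return SimulatedCohort(panel, geno, cohort, truth)


def write_cohort_files(sim: SimulatedCohort, outdir) -> dict:
    """Emit the exact formats the IO layer reads: panel TSV, dosage VCF,
    cohort TSV, truth JSON. Returns the path map."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel": outdir / "panel.tsv",
        "vcf": outdir / "dosages.vcf",
        "cohort": outdir / "cohort.tsv",
        "truth": outdir / "truth.json",
    }
    sim.panel.write_tsv(paths["panel"])
    _write_vcf(sim, paths["vcf"])
    sim.cohort.table.to_csv(paths["cohort"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(sim.truth, fh, indent=1)
    return paths


def _write_vcf(sim: SimulatedCohort, path) -> None:
    """Plain-text VCF 4.2 with per-sample DS = effect-allele dosage.

    The panel's effect allele is written as ALT so harmonization is the
    identity; missing dosages are '.'.
    """
    ids = sim.genotypes.individual_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Effect allele dosage">\n')
        for c in sorted({str(c) for c in sim.panel.table["chrom"]}, key=lambda x: (len(x), x)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids) + "\n")
        tab = sim.panel.table.reset_index(drop=True)
        keys = [
            (len(str(c)), str(c), int(p))
            for c, p in zip(tab["chrom"], tab["pos"])
        ]
        order = sorted(range(len(tab)), key=keys.__getitem__)
        for j in order:
            row = tab.iloc[j]
            col = sim.genotypes.dosages[:, j]
            ds = "\t".join("." if np.isnan(d) else f"{d:g}" for d in col)
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t"
                f"{row['other_allele']}\t{row['effect_allele']}\t.\t.\t.\tDS\t{ds}\n"
            )
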