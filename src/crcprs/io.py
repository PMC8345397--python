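"""Reading, validation and harmonization of PRS inputs.

Three tabular inputs feed the pipeline: a variant weight panel (one row per
risk variant with its effect allele and log-odds weight), per-individual
effect-allele dosages (VCF with GT/DS fields, or a plain dosage matrix), and
a cohort phenotype table. This module parses each into the internal data
model and harmonizes VCF records against the panel's effect alleles.

Conventions: coordinates are 1-based (VCF); variants are keyed by
chromosome + position + unordered allele pair, with the rsID kept for
reporting only; missing dosages are ``numpy.nan``, never 0.0, because the
downstream rescaling needs to know which variants were observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PanelFormatError",
    "ValidationError",
    "VariantPanel",
    "GenotypeMatrix",
    "CohortTable",
    "read_weights_table",
    "filter_by_imputation_r2",
    "harmonize_alleles",
    "read_dosages_vcf",
    "read_dosage_matrix",
    "write_dosage_matrix",
    "read_cohort_table",
    "GROUPS",
]

GROUPS = ("control", "sporadic_crc", "fcrc", "sp")

PANEL_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "eaf",
    "imputation_r2",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class PanelFormatError(ValueError):
    """The input file does not have the expected tabular structure."""


class ValidationError(ValueError):
    """The input parsed but violates a content invariant."""


@dataclass
class VariantPanel:
    """Weight table for the risk-variant panel.

    ``table`` columns: variant_id, chrom, pos, effect_allele, other_allele,
    beta (per-allele log odds ratio), eaf (effect-allele frequency),
    imputation_r2 (NaN for directly genotyped variants), genotyped (bool),
    included (bool). ``exclusions`` records every variant dropped by a QC
    step, with a machine-readable reason.
    """

    table: pd.DataFrame
    exclusions: list[dict] = field(default_factory=list)

    @property
    def n_variants(self) -> int:
        return len(self.table)

    @property
    def n_included(self) -> int:
        return int(self.table["included"].sum())

    @property
    def included(self) -> pd.DataFrame:
        return self.table[self.table["included"]]

    def copy(self) -> "VariantPanel":
        return VariantPanel(self.table.copy(), list(self.exclusions))

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out["imputation_r2"] = out["imputation_r2"].where(
            ~out["genotyped"], "genotyped"
        )
        out.drop(columns=["genotyped"]).to_csv(path, sep="\t", index=False)


@dataclass
class GenotypeMatrix:
    """Individuals x variants effect-allele dosage matrix.

    Dosages are floats in [0, 2]; missing entries are ``nan``. Column order
    matches the panel the matrix was built against; row order matches the
    cohort table.
    """

    individual_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.individual_ids), len(self.variant_ids)):
            raise ValidationError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.individual_ids)} individuals x "
                f"{len(self.variant_ids)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad):
            raise ValidationError("dosages outside [0, 2]")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)


@dataclass
class CohortTable:
    """Per-individual group labels, covariates and clinical flags."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"individual_id", "group", "sex", "age"}
        missing = required - set(self.table.columns)
        if missing:
            raise PanelFormatError(f"cohort table missing columns: {sorted(missing)}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        if self.table["individual_id"].duplicated().any():
            dup = self.table.loc[
                self.table["individual_id"].duplicated(), "individual_id"
            ].iloc[0]
            raise ValidationError(f"duplicated individual_id: {dup!r}")

    def group_counts(self) -> dict:
        return self.table["group"].value_counts().to_dict()

    @property
    def n(self) -> int:
        return len(self.table)


def read_weights_table(path) -> VariantPanel:
    """Read and validate a variant weight panel from TSV/CSV.

    The ``imputation_r2`` column accepts either a float in [0, 1] or the
    literal string ``genotyped`` for array-typed variants.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except (OSError, pd.errors.ParserError) as exc:
        raise PanelFormatError(f"cannot parse weights table {path}: {exc}") from exc
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise PanelFormatError(f"weights table missing columns: {sorted(missing)}")
    df = df[list(PANEL_COLUMNS)].copy()
    dup = df["variant_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicated variant_id: {df.loc[dup, 'variant_id'].iloc[0]!r}"
        )
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].str.upper().str.strip()
        bad = ~df[col].str.fullmatch(r"[ACGT]+")
        if bad.any():
            raise ValidationError(
                f"malformed allele for {df.loc[bad, 'variant_id'].iloc[0]}"
            )
    same = df["effect_allele"] == df["other_allele"]
    if same.any():
        raise ValidationError(
            f"effect allele equals other allele for {df.loc[same, 'variant_id'].iloc[0]}"
        )
    df["pos"] = pd.to_numeric(df["pos"], errors="raise").astype(int)
    df["beta"] = pd.to_numeric(df["beta"], errors="raise")
    df["eaf"] = pd.to_numeric(df["eaf"], errors="raise")
    if ((df["eaf"] < 0) | (df["eaf"] > 1)).any():
        bad_id = df.loc[(df["eaf"] < 0) | (df["eaf"] > 1), "variant_id"].iloc[0]
        raise ValidationError(f"eaf outside [0, 1] for {bad_id}")
    r2_raw = df["imputation_r2"].astype(str).str.strip().str.lower()
    genotyped = r2_raw == "genotyped"
    r2 = pd.to_numeric(df["imputation_r2"].where(~genotyped), errors="coerce")
    missing_r2 = ~genotyped & r2.isna()
    if missing_r2.any():
        raise ValidationError(
            "imputation_r2 missing for non-genotyped variant "
            f"{df.loc[missing_r2, 'variant_id'].iloc[0]}"
        )
    if ((r2 < 0) | (r2 > 1)).any():
        raise ValidationError("imputation_r2 outside [0, 1]")
    df["imputation_r2"] = r2
    df["genotyped"] = genotyped.to_numpy()
    df["included"] = True
    return VariantPanel(df.reset_index(drop=True))


def filter_by_imputation_r2(panel: VariantPanel, threshold: float = 0.3) -> VariantPanel:
    """Exclude imputed variants with imputation R^2 strictly below ``threshold``.

    Directly genotyped variants are always retained. The rule is
    strictly-less-than: a variant with R^2 exactly at the threshold stays in.
    Idempotent, and monotone in the threshold (raising it never re-includes
    a variant already excluded).
    """
    if not (0 < threshold <= 1):
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    out = panel.copy()
    t = out.table
    drop = t["included"] & ~t["genotyped"] & (t["imputation_r2"] < threshold)
    for _, row in t[drop].iterrows():
        out.exclusions.append(
            {
                "variant_id": row["variant_id"],
                "reason": "imputation_r2_below_threshold",
                "imputation_r2": float(row["imputation_r2"]),
                "threshold": threshold,
            }
        )
    t.loc[drop, "included"] = False
    if out.n_included == 0:
        warnings.warn("all variants excluded by imputation R^2 filter")
    return out


def harmonize_alleles(
    record_alleles: tuple,
    record_dosage: float,
    panel_variant,
    ambiguity_policy: str = "drop",
):
    """Orient a VCF ALT-dosage onto the panel's effect allele.

    ``record_dosage`` counts ALT copies. If the effect allele is ALT the
    dosage passes through; if it is REF the dosage flips to ``2 - dosage``.
    Strand-ambiguous pairs (A/T, C/G) are unresolvable without frequency
    information and are set missing under the default ``drop`` policy.
    Irreconcilable allele pairs always degrade to missing. Returns
    ``(dosage_or_nan, reason_or_None)``.
    """
    if ambiguity_policy not in ("drop", "keep"):
        raise ValidationError(f"unknown ambiguity_policy {ambiguity_policy!r}")
    ref, alt = (a.upper() for a in record_alleles)
    eff = panel_variant["effect_allele"]
    oth = panel_variant["other_allele"]
    ambiguous = {eff, oth} in ({"A", "T"}, {"C", "G"})
    if ambiguous and ambiguity_policy == "drop":
        return np.nan, "strand_ambiguous"
    if np.isnan(record_dosage):
        return np.nan, None
    if (eff, oth) == (alt, ref):
        return float(record_dosage), None
    if (eff, oth) == (ref, alt):
        return 2.0 - float(record_dosage), None
    return np.nan, "allele_mismatch"


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele)


def read_dosages_vcf(path, panel: VariantPanel, ambiguity_policy: str = "drop") -> GenotypeMatrix:
    """Extract effect-allele dosages for the included panel variants from a VCF.

    Records are matched by chromosome + position + unordered allele pair.
    The DS (imputed dosage) FORMAT field is preferred over GT when both are
    present. Panel variants with no matching record become all-missing
    columns, with a warning recorded on the returned matrix.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except OSError as exc:
        raise OSError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if len(samples) == 0:
        raise ValidationError(f"VCF {path} contains no samples")
    inc = panel.included.reset_index(drop=True)
    key_to_col = {}
    for j, row in inc.iterrows():
        key = (str(row["chrom"]), int(row["pos"]), frozenset((row["effect_allele"], row["other_allele"])))
        key_to_col[key] = j
    dosages = np.full((len(samples), len(inc)), np.nan)
    seen = np.zeros(len(inc), dtype=bool)
    warn: list[str] = []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        key = (str(v.CHROM), int(v.POS), frozenset((v.REF.upper(), v.ALT[0].upper())))
        j = key_to_col.get(key)
        if j is None:
            continue
        ds = v.format("DS")
        if ds is not None:
            alt_dose = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            gt = np.asarray(v.gt_types)
            alt_dose = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        pv = inc.iloc[j]
        col = np.empty(len(samples))
        reason = None
        for k, d in enumerate(alt_dose):
            col[k], r = harmonize_alleles(
                (v.REF, v.ALT[0]), d, pv, ambiguity_policy=ambiguity_policy
            )
            reason = reason or r
        if reason is not None:
            warn.append(f"{pv['variant_id']}: {reason}")
        dosages[:, j] = col
        seen[j] = True
    for j in np.flatnonzero(~seen):
        warn.append(f"{inc.iloc[j]['variant_id']}: not found in VCF")
    return GenotypeMatrix(samples, list(inc["variant_id"]), dosages, warn)


def write_dosage_matrix(geno: GenotypeMatrix, path) -> None:
    """Write the internal dosage matrix format: TSV, rows = individuals."""
    df = pd.DataFrame(geno.dosages, columns=geno.variant_ids)
    df.insert(0, "individual_id", geno.individual_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_dosage_matrix(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], float_precision="round_trip")
    if "individual_id" not in df.columns:
        raise PanelFormatError("dosage matrix missing individual_id column")
    ids = df["individual_id"].astype(str).tolist()
    vids = [c for c in df.columns if c != "individual_id"]
    return GenotypeMatrix(ids, vids, df[vids].to_numpy(dtype=float))


def read_cohort_table(path) -> CohortTable:
    df = pd.read_csv(path, sep=None, engine="python")
    df["individual_id"] = df["individual_id"].astype(str)
    return CohortTable(df)
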