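"""Cohort ingestion, quality control and the per-SNP scan pipeline.

The scan mirrors how the gamma machinery is meant to be used on a real
X-chromosome cohort of unrelated females: quality-control filters
(individual missingness, SNP missingness, minor-allele frequency, exact
Hardy-Weinberg test), a Levene association prescreen per SNP x trait, and
gamma point estimates with LR / Fieller / delta confidence regions for
the SNPs that pass the prescreen — either associated with a single trait
at the Bonferroni level, or with two or more traits at a (laxer)
multi-trait level.

Genotypes are additive codes 0/1/2 counting a declared focal allele, with
``NA`` for missing; supported on-disk formats are delimited tables
(CSV/TSV, genotype columns named ``<snp>_<allele>``) and the PLINK-RAW
dosage dialect (``FID IID PAT MAT SEX PHENOTYPE`` then ``<snp>_<allele>``
columns).  Sex is coded 2/F/female for females (PLINK convention);
unrelatedness is taken on trust from the caller's pedigree bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import intervals
from .estimate import NoAssociationError, estimate_gamma
from .hypotheses import hwe_test, levene_test, maf
from .model import DegenerateGroupError, QuantSample, fit_full

logger = logging.getLogger(__name__)

__all__ = [
    "CohortTable",
    "QCReport",
    "read_cohort",
    "write_cohort",
    "qc_filter",
    "scan",
]

_FEMALE_CODES = {"2", "f", "female"}
_PLINK_FIXED = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _is_female(sex_series: pd.Series) -> pd.Series:
    return sex_series.astype(str).str.strip().str.lower().isin(_FEMALE_CODES)


@dataclass
class CohortTable:
    """Typed cohort: subject metadata, trait values and SNP dosage codes.

    ``genotypes`` holds one float column per SNP (0/1/2 with NaN missing)
    indexed like ``subjects``; ``snp_info`` records the counted (focal)
    and other allele labels per SNP.
    """

    subjects: pd.DataFrame  # per-subject: sex + traits + covariates
    genotypes: pd.DataFrame  # per-subject x per-SNP dosage of the counted allele
    snp_info: pd.DataFrame  # per-SNP: counted_allele, other_allele, position
    traits: list = field(default_factory=list)
    covariates: list = field(default_factory=list)

    def __post_init__(self):
        if not self.subjects.index.equals(self.genotypes.index):
            raise ValueError("subjects and genotypes must share the subject index")
        vals = self.genotypes.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"invalid genotype code {vals[i, j]!r} for subject "
                f"{self.subjects.index[i]!r}, SNP {self.genotypes.columns[j]!r}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def snps(self) -> list:
        return list(self.genotypes.columns)

    def females(self) -> "CohortTable":
        """Restrict to female subjects (sex code 2/F/female), logged."""
        keep = _is_female(self.subjects["sex"])
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropping %d non-female subjects", dropped)
        return CohortTable(
            self.subjects.loc[keep],
            self.genotypes.loc[keep],
            self.snp_info,
            self.traits,
            self.covariates,
        )


def _parse_snp_column(name: str):
    if "_" not in name:
        raise ValueError(
            f"genotype column {name!r} lacks the '<snp>_<allele>' counted-allele "
            "suffix"
        )
    snp, allele = name.rsplit("_", 1)
    return snp, allele


def _check_codes(raw: pd.DataFrame, id_index) -> pd.DataFrame:
    geno = raw.apply(pd.to_numeric, errors="coerce")
    vals = geno.to_numpy(dtype=float)
    ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
    # non-numeric strings other than the NA sentinel also coerce to NaN;
    # flag those explicitly instead of silently treating them as missing
    declared_missing = raw.isna() | raw.apply(
        lambda col: col.astype(str).str.strip().isin(["NA", "nan", ""])
    )
    ok &= ~(np.isnan(vals) & ~declared_missing.to_numpy())
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ValueError(
            f"invalid genotype code {raw.iloc[i, j]!r} at subject "
            f"{id_index[i]!r}, column {raw.columns[j]!r} (expected 0/1/2/NA)"
        )
    return geno.astype(float)


def read_cohort(
    path,
    format: str = "csv",
    traits: Optional[Sequence[str]] = None,
    covariates: Optional[Sequence[str]] = None,
    id_col: str = "IID",
    sex_col: str = "SEX",
) -> CohortTable:
    """Read a cohort table from CSV/TSV or a PLINK-RAW-style file.

    Genotype columns are recognized by the ``<snp>_<allele>`` naming, the
    counted allele being the focal allele D; missing genotypes are ``NA``.
    Columns named in ``traits`` / ``covariates`` are carried as subject
    data.  Malformed genotype entries raise with the offending row and
    column named.
    """
    if format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
        missing = [c for c in _PLINK_FIXED if c not in df.columns]
        if missing:
            raise ValueError(f"PLINK-RAW header lacks columns {missing}")
        traits = list(traits) if traits else ["PHENOTYPE"]
        snp_cols = [c for c in df.columns if c not in _PLINK_FIXED]
    elif format in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if format == "csv" else "\t", dtype=str)
        if id_col not in df.columns or sex_col not in df.columns:
            raise ValueError(f"header must contain {id_col!r} and {sex_col!r}")
        traits = list(traits) if traits else []
        claimed = {id_col, sex_col, *traits, *(covariates or [])}
        snp_cols = [c for c in df.columns if c not in claimed]
    else:
        raise ValueError(f"unknown format {format!r}")
    covariates = list(covariates) if covariates else []
    df = df.set_index(id_col if format != "plink_raw" else "IID")
    info = pd.DataFrame(
        [_parse_snp_column(c) for c in snp_cols],
        columns=["snp", "counted_allele"],
    )
    info["other_allele"] = ""
    info = info.set_index("snp")
    geno = _check_codes(df[snp_cols], df.index)
    geno.columns = info.index
    subj_cols = {}
    subj_cols["sex"] = df[sex_col if format != "plink_raw" else "SEX"]
    for c in traits + covariates:
        subj_cols[c] = pd.to_numeric(df[c], errors="coerce")
    subjects = pd.DataFrame(subj_cols, index=df.index)
    logger.info(
        "read cohort: %d subjects, %d SNPs, traits=%s", len(df), len(snp_cols), traits
    )
    return CohortTable(subjects, geno, info, traits, covariates)


def write_cohort(table: CohortTable, path, format: str = "csv") -> None:
    """Write a cohort back to a delimited table (round-trips read_cohort)."""
    sep = "," if format == "csv" else "\t"
    out = table.subjects.copy()
    out.insert(0, "SEX", out.pop("sex"))
    geno = table.genotypes.copy()
    geno.columns = [
        f"{snp}_{table.snp_info.loc[snp, 'counted_allele']}" for snp in geno.columns
    ]
    merged = pd.concat([out, geno], axis=1)
    merged.index.name = "IID"
    with np.errstate(invalid="ignore"):
        merged.to_csv(path, sep=sep, na_rep="NA", float_format="%.10g")


@dataclass
class QCReport:
    """Removal counts per quality-control rule, in application order."""

    n_subjects_in: int
    n_snps_in: int
    subjects_removed_missingness: int = 0
    snps_removed_missingness: int = 0
    snps_removed_maf: int = 0
    snps_removed_hwe: int = 0
    n_subjects_out: int = 0
    n_snps_out: int = 0


def qc_filter(
    table: CohortTable,
    ind_miss: float = 0.10,
    snp_miss: float = 0.10,
    maf_min: float = 0.05,
    hwe_alpha: float = 1e-4,
):
    """Quality-control filters, applied in order.

    1. subjects with genotype missingness above ``ind_miss`` are excluded;
    2. SNPs with missingness above ``snp_miss`` are deleted;
    3. SNPs with minor-allele frequency below ``maf_min`` or an exact
       Hardy-Weinberg test p-value below ``hwe_alpha`` are excluded.

    Returns (filtered CohortTable, QCReport).  Raises if every subject or
    every SNP would be removed.
    """
    report = QCReport(n_subjects_in=table.n_subjects, n_snps_in=len(table.snps))
    geno = table.genotypes
    subj_rate = geno.isna().mean(axis=1)
    keep_subj = subj_rate <= ind_miss
    report.subjects_removed_missingness = int((~keep_subj).sum())
    if not keep_subj.any():
        raise ValueError("QC removed every subject (individual missingness)")
    geno = geno.loc[keep_subj]

    snp_rate = geno.isna().mean(axis=0)
    keep_snp = snp_rate <= snp_miss
    report.snps_removed_missingness = int((~keep_snp).sum())
    geno = geno.loc[:, keep_snp]

    keep = []
    for snp in geno.columns:
        g = geno[snp].dropna().to_numpy()
        if g.size == 0 or maf(g) < maf_min:
            report.snps_removed_maf += 1
            continue
        counts = np.bincount(g.astype(int), minlength=3)[:3]
        if hwe_test(*counts) < hwe_alpha:
            report.snps_removed_hwe += 1
            continue
        keep.append(snp)
    if not keep:
        raise ValueError("QC removed every SNP")
    filtered = CohortTable(
        table.subjects.loc[geno.index],
        geno[keep],
        table.snp_info.loc[keep],
        table.traits,
        table.covariates,
    )
    report.n_subjects_out = filtered.n_subjects
    report.n_snps_out = len(keep)
    logger.info("QC: %s", report)
    return filtered, report


def _render(region) -> str:
    return str(region)


def scan(
    table: CohortTable,
    traits: Optional[Sequence[str]] = None,
    alpha_single: Optional[float] = None,
    alpha_multi: float = 1e-3,
    ci_level: float = 0.95,
    levene_center: str = "mean",
    bonferroni_divisor: Optional[int] = None,
) -> pd.DataFrame:
    """Per-SNP prescreen and gamma estimation over a QC'd female cohort.

    Every SNP x trait pair gets a Levene prescreen p-value (complete cases
    per SNP).  A SNP receives gamma estimates and the three confidence
    regions for a trait when either the pair passes the single-trait
    Bonferroni threshold (``alpha_single``, default 0.05 divided by the
    number of SNPs actually tested) or the SNP is associated with two or
    more traits at ``alpha_multi``.  Per-SNP failures are recorded in the
    ``status`` column and the scan continues.
    """
    table = table.females()
    traits = list(traits) if traits else table.traits
    if not traits:
        raise ValueError("no trait columns to scan")
    snps = table.snps
    divisor = bonferroni_divisor or len(snps)
    if alpha_single is None:
        alpha_single = 0.05 / divisor
    alpha_ci = 1.0 - ci_level

    # prescreen every SNP x trait
    pvals = {}
    for snp in snps:
        for trait in traits:
            sub = pd.DataFrame(
                {"y": table.subjects[trait], "g": table.genotypes[snp]}
            ).dropna()
            try:
                pvals[snp, trait] = levene_test(
                    sub["y"].to_numpy(), sub["g"].to_numpy(), center=levene_center
                ).pvalue
            except ValueError:
                pvals[snp, trait] = np.nan

    rows = []
    for snp in snps:
        g_all = table.genotypes[snp].dropna()
        counts = np.bincount(g_all.to_numpy().astype(int), minlength=3)[:3]
        snp_maf = maf(g_all.to_numpy())
        hwe_p = hwe_test(*counts)
        counted = table.snp_info.loc[snp, "counted_allele"]
        other = table.snp_info.loc[snp, "other_allele"]
        position = (
            table.snp_info.loc[snp, "position"]
            if "position" in table.snp_info.columns
            else np.nan
        )
        p_counted = g_all.to_numpy().sum() / (2.0 * len(g_all))
        minor, major = (counted, other) if p_counted <= 0.5 else (other, counted)
        n_multi = sum(
            1 for t in traits if pvals[snp, t] == pvals[snp, t] and pvals[snp, t] < alpha_multi
        )
        for trait in traits:
            p = pvals[snp, trait]
            fired_single = p == p and p < alpha_single
            fired_multi = n_multi >= 2 and p == p and p < alpha_multi
            row = {
                "snp": snp,
                "position": position,
                "minor": minor,
                "major": major,
                "maf": snp_maf,
                "hwe_pvalue": hwe_p,
                "trait": trait,
                "levene_pvalue": p,
                "gamma_hat": np.nan,
                "ci_lr": "",
                "ci_fieller": "",
                "ci_delta": "",
                "status": "prescreen_only",
            }
            if fired_single or fired_multi:
                sub = pd.DataFrame(
                    {"y": table.subjects[trait], "g": table.genotypes[snp]}
                ).dropna()
                sample = QuantSample(
                    sub["y"].to_numpy(),
                    sub["g"].to_numpy().astype(int),
                    focal_allele=str(counted),
                )
                try:
                    fit = fit_full(sample)
                    est = estimate_gamma(fit)
                    row["gamma_hat"] = est.gamma_hat
                    row["ci_lr"] = _render(intervals.lr_ci(sample, alpha_ci))
                    row["ci_fieller"] = _render(intervals.fieller_ci(fit, alpha_ci))
                    row["ci_delta"] = _render(intervals.delta_ci(est, alpha_ci))
                    row["status"] = "estimated"
                except (DegenerateGroupError, NoAssociationError) as exc:
                    row["status"] = f"failed: {exc}"
                    logger.warning("SNP %s/%s: %s", snp, trait, exc)
            rows.append(row)
    return pd.DataFrame(rows)
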