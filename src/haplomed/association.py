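"""Covariate-adjusted lipid association under the additive genetic model.

Lipid outcomes (TG, HDL-C) are log-transformed before regression and fitted by
ordinary least squares on a genetic dosage plus age, sex, BMI and smoking,
with an optional further adjustment for log TG when HDL-C is the outcome.
Missing data are handled by listwise deletion at the regression stage.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import CollinearityError, EmptyResultError
from .genotypes import GenotypeMatrix
from .phasing import HaplotypeModel, hwe_test

__all__ = [
    "CohortTable",
    "RegressionFit",
    "ScanResult",
    "DEFAULT_COVARIATES",
    "qc_filter",
    "fit_lipid_model",
    "haplotype_association_table",
    "snp_scan",
    "cohort_summary",
]

DEFAULT_COVARIATES = ("age", "sex", "bmi", "smoking")
REQUIRED_COLUMNS = ("id", "age", "sex", "bmi", "smoking", "tg", "hdl")
GENOME_WIDE_ALPHA = 5e-8


@dataclass
class CohortTable:
    """Covariates and lipid phenotypes, one row per individual.

    Columns: ``id, age, sex, bmi, smoking, tg, hdl`` and optionally
    ``tc, ldl``.  Sex and smoking are coded 1 = male / 1 = current smoker;
    lipids are on the natural (mg/dL) scale and must be positive where
    present.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table lacks columns: {missing}")
        for col in ("tg", "hdl"):
            vals = self.data[col].dropna()
            if (vals <= 0).any():
                raise ValueError(f"{col} must be strictly positive where present")
        if self.data["id"].duplicated().any():
            raise ValueError("sample ids must be unique")
        self.data = self.data.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data["id"]]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class RegressionFit:
    """Coefficients, standard errors and Wald p-values for one linear model."""

    outcome_name: str
    term_names: list[str]
    coefficients: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    n_used: int
    adjusted_for_tg: bool = False

    def __getitem__(self, term: str) -> tuple[float, float, float]:
        i = self.term_names.index(term)
        return (
            float(self.coefficients[i]),
            float(self.std_errors[i]),
            float(self.p_values[i]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.term_names,
                "coefficient": self.coefficients,
                "std_error": self.std_errors,
                "p_value": self.p_values,
            }
        )


@dataclass
class ScanResult:
    """Per-SNP additive-model scan, sorted by genomic position."""

    table: pd.DataFrame
    threshold: float
    adjusted_for_tg: bool

    @property
    def hits(self) -> pd.DataFrame:
        return self.table[self.table["significant"].fillna(False)]


def _log(x, base: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if base == math.e:
        return np.log(x)
    return np.log(x) / np.log(base)


def qc_filter(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.05,
    missing_max: float = 0.03,
    hwe_p_min: float = 1e-6,
    hwe_method: str = "chisq",
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Standard per-SNP QC: missingness, then MAF, then HWE.

    A SNP is excluded when its call missingness exceeds ``missing_max``, its
    minor allele frequency is below ``maf_min``, or its Hardy-Weinberg test
    p-value is below ``hwe_p_min``.  Filters are applied in that order and
    each excluded SNP carries the first failing rule as its reason.

    Returns the filtered matrix and a per-SNP report.
    """
    if genotypes.n_snps == 0:
        raise EmptyResultError("empty genotype matrix")
    miss = genotypes.missing_rate()
    maf = genotypes.maf()
    rows = []
    keep = []
    for j, sid in enumerate(genotypes.snp_ids):
        reason = None
        if miss[j] > missing_max:
            reason = "missingness"
        elif not np.isfinite(maf[j]) or maf[j] < maf_min:
            reason = "maf"
        hwe_p = np.nan
        if reason is None:
            hwe_p = hwe_test(genotypes, sid, method=hwe_method)
            if hwe_p < hwe_p_min:
                reason = "hwe"
        rows.append(
            {
                "snp_id": sid,
                "missing_rate": miss[j],
                "maf": maf[j],
                "hwe_p": hwe_p,
                "status": "retained" if reason is None else "excluded",
                "reason": reason or "",
            }
        )
        if reason is None:
            keep.append(sid)
    report = pd.DataFrame(rows)
    if not keep:
        raise EmptyResultError("all SNPs excluded by QC")
    return genotypes.subset(snp_ids=keep), report


def fit_lipid_model(
    cohort: CohortTable,
    exposure: np.ndarray,
    outcome: str = "hdl",
    adjust_tg: bool = False,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    exposure_name: str = "dosage",
    log_base: float = math.e,
) -> RegressionFit:
    """OLS of log(outcome) on a genetic dosage plus covariates.

    ``adjust_tg`` adds log TG to the model (only meaningful when the outcome
    is HDL-C).  Rows with any missing model variable are dropped (listwise
    deletion).  Raises :class:`CollinearityError` on a rank-deficient design.
    """
    if outcome not in ("tg", "hdl"):
        raise ValueError("outcome must be 'tg' or 'hdl'")
    exposure = np.asarray(exposure, dtype=float)
    if exposure.shape[0] != len(cohort):
        raise ValueError("exposure is not aligned with the cohort")
    df = cohort.data
    X = pd.DataFrame({exposure_name: exposure})
    for cov in covariates:
        X[cov] = df[cov].to_numpy(dtype=float)
    if adjust_tg and outcome != "tg":
        with np.errstate(invalid="ignore"):
            X["log_tg"] = _log(df["tg"].to_numpy(), log_base)
    with np.errstate(invalid="ignore"):
        y = _log(df[outcome].to_numpy(), log_base)
    mask = np.isfinite(y) & np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    n_used = int(mask.sum())
    if n_used < X.shape[1] + 2:
        raise EmptyResultError("too few complete cases for the model")
    design = sm.add_constant(X.loc[mask], has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise CollinearityError(
            f"rank-deficient design for outcome {outcome}: "
            "a model term is constant or a linear combination of others"
        )
    res = sm.OLS(y[mask], design).fit()
    return RegressionFit(
        outcome_name=outcome,
        term_names=list(design.columns),
        coefficients=res.params.to_numpy(),
        std_errors=res.bse.to_numpy(),
        p_values=res.pvalues.to_numpy(),
        n_used=n_used,
        adjusted_for_tg=bool(adjust_tg and outcome != "tg"),
    )


def haplotype_association_table(
    model: HaplotypeModel,
    cohort: CohortTable,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    log_base: float = math.e,
) -> pd.DataFrame:
    """Per-haplotype lipid association table.

    For each retained haplotype, fits three covariate-adjusted models with
    that haplotype's expected dosage as the single genetic term: log TG, log
    HDL without TG adjustment, and log HDL with TG adjustment.  Rows report
    the haplotype's alleles, frequency, the TG and HDL coefficients with
    p-values, and the TG-adjusted HDL p-value (``hdl_p_adj_tg``).
    """
    if len(model.haplotypes) < 2:
        raise ValueError("need at least two retained haplotypes")
    rows = []
    for h, hap in enumerate(model.haplotypes):
        dose = model.dosage[:, h]
        fit_tg = fit_lipid_model(
            cohort, dose, "tg", covariates=covariates, log_base=log_base
        )
        fit_hdl = fit_lipid_model(
            cohort, dose, "hdl", covariates=covariates, log_base=log_base
        )
        fit_hdl_tg = fit_lipid_model(
            cohort, dose, "hdl", adjust_tg=True, covariates=covariates,
            log_base=log_base,
        )
        c_tg, _, p_tg = fit_tg["dosage"]
        c_hdl, _, p_hdl = fit_hdl["dosage"]
        _, _, p1 = fit_hdl_tg["dosage"]
        rows.append(
            {
                "haplotype": model.labels[h],
                "alleles": hap,
                "frequency": model.freqs[h],
                "tg_coef": c_tg,
                "tg_p": p_tg,
                "hdl_coef": c_hdl,
                "hdl_p": p_hdl,
                "hdl_p_adj_tg": p1,
            }
        )
    return pd.DataFrame(rows)


def snp_scan(
    genotypes: GenotypeMatrix,
    cohort: CohortTable,
    outcome: str = "hdl",
    adjust_tg: bool = False,
    threshold: float = GENOME_WIDE_ALPHA,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    log_base: float = math.e,
) -> ScanResult:
    """Per-SNP additive-model scan of log HDL-C (optionally TG-adjusted).

    The effect allele is the alt allele; SNPs whose fit fails (for example
    monomorphic sites) are flagged with a reason and carry no p-value.
    Output is sorted by (chromosome, position) for Manhattan plotting.
    """
    lookup = {s: i for i, s in enumerate(cohort.sample_ids)}
    order = [lookup[s] for s in genotypes.sample_ids]
    aligned = CohortTable(cohort.data.iloc[order].reset_index(drop=True))
    chrom = genotypes.chrom or ["?"] * genotypes.n_snps
    pos = genotypes.pos or list(range(genotypes.n_snps))
    rows = []
    for j, sid in enumerate(genotypes.snp_ids):
        row = {
            "chrom": chrom[j],
            "pos": pos[j],
            "snp_id": sid,
            "effect_allele": genotypes.alleles[j][1],
            "coefficient": np.nan,
            "std_error": np.nan,
            "p_value": np.nan,
            "significant": None,
            "flag": "",
        }
        try:
            fit = fit_lipid_model(
                aligned,
                genotypes.calls[:, j],
                outcome,
                adjust_tg=adjust_tg,
                covariates=covariates,
                exposure_name="allele_count",
                log_base=log_base,
            )
            coef, se, p = fit["allele_count"]
            row.update(
                coefficient=coef, std_error=se, p_value=p,
                significant=bool(p < threshold),
            )
        except (CollinearityError, EmptyResultError) as exc:
            row["flag"] = type(exc).__name__
        rows.append(row)
    table = pd.DataFrame(rows)

    def _chrom_key(c):
        c = str(c)
        return (0, int(c)) if c.isdigit() else (1, c)

    table = table.sort_values(
        by=["chrom", "pos"], key=lambda col: col.map(_chrom_key) if col.name == "chrom" else col
    ).reset_index(drop=True)
    return ScanResult(table=table, threshold=threshold, adjusted_for_tg=adjust_tg)


_SUMMARY_STYLE = {
    "age": "median_iqr",
    "bmi": "mean_sd",
    "smoking": "count_pct",
    "tc": "mean_sd",
    "ldl": "mean_sd",
    "hdl": "median_iqr",
    "tg": "median_iqr",
}


def cohort_summary(cohort: CohortTable, group_by: str = "sex") -> pd.DataFrame:
    """Descriptive cohort table by group with two-sample tests.

    Continuous variables are summarised as mean +/- SD or median (IQR)
    according to their customary presentation and compared with a two-sample
    t-test; categorical variables as counts (%) with a chi-square test.
    With a single group, only descriptives are produced.
    """
    df = cohort.data
    groups = sorted(df[group_by].dropna().unique())
    rows = [
        {
            "variable": "n",
            "overall": float(len(df)),
            **{f"group_{g}": float((df[group_by] == g).sum()) for g in groups},
            "p_value": np.nan,
            "test": "",
        }
    ]
    for var, style in _SUMMARY_STYLE.items():
        if var not in df.columns or var == group_by:
            continue
        vals = df[var]
        row = {"variable": var, "p_value": np.nan, "test": ""}

        def _describe(v):
            v = v.dropna()
            if style == "mean_sd":
                return f"{v.mean():.1f} +/- {v.std():.1f}"
            if style == "median_iqr":
                q1, q2, q3 = v.quantile([0.25, 0.5, 0.75])
                return f"{q2:.1f} ({q1:.1f}-{q3:.1f})"
            return f"{int(v.sum())} ({100 * v.mean():.1f}%)"

        row["overall"] = _describe(vals)
        by_group = [df.loc[df[group_by] == g, var].dropna() for g in groups]
        for g, v in zip(groups, by_group):
            row[f"group_{g}"] = _describe(v)
        if len(groups) >= 2:
            if style == "count_pct":
                obs = np.array([[v.sum(), len(v) - v.sum()] for v in by_group], dtype=float)
                if (obs.sum(axis=0) > 0).all():
                    _, p, _, _ = stats.chi2_contingency(obs)
                    row.update(p_value=p, test="chi2")
                else:
                    row["test"] = "skipped:degenerate"
            else:
                if any(v.std() == 0 for v in by_group):
                    row["test"] = "skipped:constant"
                else:
                    _, p = stats.ttest_ind(by_group[0], by_group[1], equal_var=False)
                    row.update(p_value=p, test="t")
        rows.append(row)
    return pd.DataFrame(rows)
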