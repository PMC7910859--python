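"""Synthetic cohort generator for the haplotype-mediation pipeline.

Emulates a biobank-style cohort: three tightly linked promoter SNPs whose
haplotypes are drawn under Hardy-Weinberg random union of gametes, covariates
with realistic marginal distributions, and log-scale lipid phenotypes wired
through an exposure -> mediator -> outcome path model:

    log TG  = b1 + alpha * d(H1) + covariates + N(0, sigma_tg^2)
    log HDL = b2 + gamma' * d(H1) + beta * log TG + covariates + N(0, sigma_hdl^2)

where ``d(H1)`` is the true dosage (0/1/2) of the effect haplotype.  A direct
path (gamma') of sign opposite to the indirect path (alpha * beta) produces
the suppression structure the mediation module is designed to detect.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import io as hio
from .association import CohortTable
from .genotypes import GenotypeMatrix

__all__ = ["SimulationConfig", "SyntheticCohort", "simulate_cohort", "write_cohort"]

#: Cohort haplotype frequencies over (rs1077834, rs1800588, rs2070895).
#: The three common haplotypes carry 99.9% of the mass; a rare fourth
#: haplotype holds the remainder so the frequencies form a distribution.
DEFAULT_HAPLOTYPE_FREQS = {"TCG": 0.613, "CTA": 0.361, "CCA": 0.025, "TTA": 0.001}

#: Focal promoter SNPs: (id, chrom, pos, ref, alt).  Ref alleles spell the
#: major haplotype TCG; positions are the promoter-region coordinates.
FOCAL_SNPS = [
    ("rs1077834", "15", 58723479, "T", "C"),
    ("rs1800588", "15", 58723675, "C", "T"),
    ("rs2070895", "15", 58723939, "G", "A"),
]

#: Covariate -> (effect on log TG, direct effect on log HDL).  Signs chosen so
#: men have higher TG and lower HDL-C, smoking raises TG and lowers HDL-C.
DEFAULT_COVARIATE_EFFECTS = {
    "age": (0.008, -0.001),
    "sex": (0.25, -0.12),
    "bmi": (0.045, -0.012),
    "smoking": (0.08, -0.04),
}

_P_MALE = 1734 / 4000
_SMOKING_RATE = {1: 0.329, 0: 0.054}  # by sex (1 = male)
_AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI = 48.0, 13.3, 20.0, 80.0
_BMI_MEAN, _BMI_SD = 24.1, 3.5
_TC_MEAN, _TC_SD = 194.4, 35.5
_LDL_MEAN, _LDL_SD = 121.2, 31.9


@dataclass
class SimulationConfig:
    """Parameters of the data-generating model.

    ``alpha`` is the haplotype -> log-TG path per dosage unit, ``beta`` the
    log-TG -> log-HDL path, and ``gamma_prime`` the direct haplotype ->
    log-HDL path.  Defaults reproduce the suppression configuration: a
    negative direct effect partially cancelled by a positive indirect effect.
    Age and BMI enter the linear predictors centred at their population
    means, so the intercepts pin the median lipid levels directly.
    """

    n_individuals: int = 4000
    haplotype_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAPLOTYPE_FREQS)
    )
    alpha: float = -0.053
    beta: float = -0.22
    gamma_prime: float = -0.033
    covariate_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    sigma_tg: float = 0.5
    sigma_hdl: float = 0.3
    intercepts: tuple[float, float] = (4.486, 5.069)
    n_null_snps: int = 0
    seed: int = 0
    effect_haplotype: str | None = None  # default: most frequent haplotype
    missing_rate: float = 0.0
    log_base: float = math.e

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        freqs = np.array(list(self.haplotype_freqs.values()), dtype=float)
        if (freqs < 0).any():
            raise ValueError("haplotype frequencies must be non-negative")
        if abs(freqs.sum() - 1.0) > 1e-12:
            raise ValueError("haplotype frequencies must sum to 1")
        lengths = {len(h) for h in self.haplotype_freqs}
        if len(lengths) != 1:
            raise ValueError("haplotype strings must share one length")
        if self.sigma_tg <= 0 or self.sigma_hdl <= 0:
            raise ValueError("residual SDs must be positive")
        if self.n_null_snps < 0:
            raise ValueError("n_null_snps must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.log_base <= 0 or self.log_base == 1.0:
            raise ValueError("log_base must be positive and != 1")

    @property
    def n_focal_snps(self) -> int:
        return len(next(iter(self.haplotype_freqs)))


@dataclass
class SyntheticCohort:
    """Generated cohort plus the hidden truth channel used only by tests."""

    genotypes: GenotypeMatrix
    true_diplotypes: np.ndarray  # (n, 2) array of haplotype strings
    cohort: CohortTable
    config: SimulationConfig

    def true_dosage(self, haplotype: str | None = None) -> np.ndarray:
        """True copy number (0/1/2) of ``haplotype`` per individual."""
        if haplotype is None:
            haplotype = self.config.effect_haplotype or max(
                self.config.haplotype_freqs, key=self.config.haplotype_freqs.get
            )
        return (self.true_diplotypes == haplotype).sum(axis=1).astype(float)


def _site_alleles(freqs: dict[str, float]) -> list[tuple[str, str]]:
    """Derive per-site (ref, alt) pairs; ref is the major-haplotype allele."""
    haps = list(freqs)
    k = len(haps[0])
    major = max(haps, key=lambda h: freqs[h])
    alleles = []
    for s in range(k):
        chars = {h[s] for h in haps}
        ref = major[s]
        others = sorted(chars - {ref})
        alleles.append((ref, others[0] if others else "N"))
    return alleles


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a cohort from the configured path model.

    Haplotypes are paired by random union of gametes (i.i.d. draws from the
    haplotype frequency distribution), so diplotypes follow Hardy-Weinberg
    proportions.  Null SNPs are unlinked biallelic sites with uniform MAF on
    [0.05, 0.5] and no phenotype effect.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    haps = list(config.haplotype_freqs)
    probs = np.array([config.haplotype_freqs[h] for h in haps])
    k = config.n_focal_snps

    gametes = rng.choice(len(haps), size=(n, 2), p=probs)
    site_alleles = _site_alleles(config.haplotype_freqs)
    # alt-allele indicator per haplotype per site
    alt_mat = np.array(
        [[1 if h[s] == site_alleles[s][1] else 0 for s in range(k)] for h in haps]
    )
    focal_calls = (alt_mat[gametes[:, 0]] + alt_mat[gametes[:, 1]]).astype(float)

    effect_hap = config.effect_haplotype or max(
        config.haplotype_freqs, key=config.haplotype_freqs.get
    )
    hap_strings = np.array(haps)
    true_diplotypes = hap_strings[gametes]
    d = (true_diplotypes == effect_hap).sum(axis=1).astype(float)

    # covariates
    sex = rng.binomial(1, _P_MALE, size=n).astype(float)
    age = _truncated_normal(rng, _AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI, n)
    bmi = _truncated_normal(rng, _BMI_MEAN, _BMI_SD, 0.0, np.inf, n)
    smoke_p = np.where(sex == 1, _SMOKING_RATE[1], _SMOKING_RATE[0])
    smoking = rng.binomial(1, smoke_p).astype(float)
    centred = {"age": age - _AGE_MEAN, "sex": sex, "bmi": bmi - _BMI_MEAN, "smoking": smoking}

    b1, b2 = config.intercepts
    lin_tg = b1 + config.alpha * d
    lin_hdl = b2 + config.gamma_prime * d
    for cov, (e_tg, e_hdl) in config.covariate_effects.items():
        lin_tg = lin_tg + e_tg * centred[cov]
        lin_hdl = lin_hdl + e_hdl * centred[cov]
    log_tg = lin_tg + rng.normal(0.0, config.sigma_tg, size=n)
    log_hdl = lin_hdl + config.beta * log_tg + rng.normal(0.0, config.sigma_hdl, size=n)
    base = config.log_base
    tg = np.power(base, log_tg) if base != math.e else np.exp(log_tg)
    hdl = np.power(base, log_hdl) if base != math.e else np.exp(log_hdl)

    tc = _truncated_normal(rng, _TC_MEAN, _TC_SD, 0.0, np.inf, n)
    ldl = _truncated_normal(rng, _LDL_MEAN, _LDL_SD, 0.0, np.inf, n)

    if k <= len(FOCAL_SNPS):
        snp_ids = [s[0] for s in FOCAL_SNPS[:k]]
        chrom = [s[1] for s in FOCAL_SNPS[:k]]
        pos = [s[2] for s in FOCAL_SNPS[:k]]
    else:
        snp_ids = [f"focal{j + 1}" for j in range(k)]
        chrom = ["15"] * k
        pos = [58723479 + 100 * j for j in range(k)]

    calls = focal_calls
    alleles = list(site_alleles)
    if config.n_null_snps:
        m = config.n_null_snps
        mafs = rng.uniform(0.05, 0.5, size=m)
        null_calls = rng.binomial(2, mafs, size=(n, m)).astype(float)
        calls = np.hstack([calls, null_calls])
        alleles += [("A", "G")] * m
        snp_ids = snp_ids + [f"null{j + 1}" for j in range(m)]
        chrom = chrom + [str((j % 14) + 1) for j in range(m)]
        pos = pos + [100_000 * (j + 1) for j in range(m)]

    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls = calls.copy()
        calls[mask] = np.nan

    sample_ids = [f"TWB{i + 1:05d}" for i in range(n)]
    genotypes = GenotypeMatrix(
        snp_ids=snp_ids, alleles=alleles, calls=calls, sample_ids=sample_ids,
        chrom=chrom, pos=pos,
    )
    pheno = pd.DataFrame(
        {
            "id": sample_ids,
            "age": age,
            "sex": sex.astype(int),
            "bmi": bmi,
            "smoking": smoking.astype(int),
            "tg": tg,
            "hdl": hdl,
            "tc": tc,
            "ldl": ldl,
        }
    )
    return SyntheticCohort(
        genotypes=genotypes,
        true_diplotypes=true_diplotypes,
        cohort=CohortTable(pheno),
        config=config,
    )


def write_cohort(cohort: SyntheticCohort, out_prefix: str | os.PathLike) -> dict[str, str]:
    """Write VCF + genotype TSV + phenotype TSV + test-only truth sidecar.

    Returns a mapping of artifact name to path.
    """
    prefix = str(out_prefix)
    parent = os.path.dirname(prefix)
    if parent:
        os.makedirs(parent, exist_ok=True)
    paths = {
        "vcf": prefix + ".vcf",
        "genotypes_tsv": prefix + ".genotypes.tsv",
        "phenotypes_tsv": prefix + ".phenotypes.tsv",
        "truth_tsv": prefix + ".truth.tsv",
    }
    hio.write_vcf(cohort.genotypes, paths["vcf"])
    hio.write_genotype_tsv(cohort.genotypes, paths["genotypes_tsv"])
    hio.write_phenotypes(cohort.cohort.data, paths["phenotypes_tsv"])
    cfg = cohort.config
    with open(paths["truth_tsv"], "w") as fh:
        fh.write("# TEST-ONLY truth sidecar: hidden diplotypes and generating parameters\n")
        fh.write(f"# alpha={cfg.alpha}\tbeta={cfg.beta}\tgamma_prime={cfg.gamma_prime}\n")
        fh.write(f"# sigma_tg={cfg.sigma_tg}\tsigma_hdl={cfg.sigma_hdl}\tseed={cfg.seed}\n")
        fh.write("id\thap1\thap2\n")
        for sid, (h1, h2) in zip(cohort.genotypes.sample_ids, cohort.true_diplotypes):
            fh.write(f"{sid}\t{h1}\t{h2}\n")
    return paths
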