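"""Four-criterion mediation analysis with Sobel test and suppression detection.

The exposure X (haplotype dosage), mediator M (log TG) and outcome Y
(log HDL-C) are related through three covariate-adjusted linear models:

    M ~ X + C          -> alpha        (criterion 1: X-M association)
    Y ~ X + M + C      -> beta, gamma' (criterion 2: M-Y given X; direct path)
    Y ~ X + C          -> total        (criterion 3: X-Y total effect)

The indirect (mediation) effect is alpha * beta, with the identity
total = alpha * beta + gamma' holding exactly on complete cases.  Criterion 4
tests the indirect effect with the Sobel z-test.  Mediation requires all four
criteria plus |gamma'| < |total|; suppression requires criteria 1, 2 and 4,
opposing signs of the direct and indirect effects, and |gamma'| > |total| —
the total effect itself may be null, since the two paths can cancel.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    DEFAULT_COVARIATES,
    CohortTable,
    RegressionFit,
    fit_lipid_model,
)
from .exceptions import CollinearityError

__all__ = [
    "MediationResult",
    "sobel_se",
    "run_mediation",
    "mediation_from_estimates",
    "bootstrap_indirect_ci",
]


def sobel_se(
    alpha: float,
    se_alpha: float,
    beta: float,
    se_beta: float,
    aroian: bool = False,
) -> float:
    """Delta-method standard error of the indirect effect alpha * beta.

    The first-order form is sqrt(beta^2 SEa^2 + alpha^2 SEb^2); the Aroian
    variant adds the second-order SEa^2 SEb^2 term and is never smaller.
    """
    if se_alpha <= 0 or se_beta <= 0:
        raise ValueError("standard errors must be positive")
    var = beta * beta * se_alpha * se_alpha + alpha * alpha * se_beta * se_beta
    if aroian:
        var += se_alpha * se_alpha * se_beta * se_beta
    return math.sqrt(var)


@dataclass
class MediationResult:
    """Path estimates, Sobel test, criterion flags and classification."""

    alpha: float
    se_alpha: float
    p_alpha: float
    beta: float
    se_beta: float
    p_beta: float
    gamma_prime: float
    se_gamma_prime: float
    p_gamma_prime: float
    indirect: float
    se_indirect: float
    total: float
    p_total: float
    sobel_z: float
    sobel_p: float
    criteria: tuple[bool, bool, bool, bool]
    classification: str
    n_used: int = 0
    total_fitted: float = float("nan")
    se_total: float = float("nan")

    def __post_init__(self) -> None:
        if abs(self.indirect - self.alpha * self.beta) > 1e-12:
            raise ValueError("indirect effect must equal alpha * beta")
        if abs(self.total - (self.indirect + self.gamma_prime)) > 1e-12:
            raise ValueError("total effect must equal indirect + direct")
        if self.classification not in ("none", "mediation", "suppression"):
            raise ValueError(f"bad classification: {self.classification}")

    def to_frame(self) -> pd.DataFrame:
        """Criterion-labelled rows mirroring the standard mediation table."""
        rows = [
            ("Criterion 1", "alpha", self.alpha, self.se_alpha, self.p_alpha),
            ("Criterion 2", "beta", self.beta, self.se_beta, self.p_beta),
            ("Direct", "gamma_prime", self.gamma_prime, self.se_gamma_prime, self.p_gamma_prime),
            ("Criterion 3", "total (alpha*beta + gamma_prime)", self.total, self.se_total, self.p_total),
            ("Criterion 4", "indirect (alpha*beta)", self.indirect, self.se_indirect, self.sobel_p),
        ]
        df = pd.DataFrame(
            rows, columns=["criterion", "effect", "coefficient", "std_error", "p_value"]
        )
        df.attrs["sobel_z"] = self.sobel_z
        df.attrs["classification"] = self.classification
        return df


def _classify(
    criteria: tuple[bool, bool, bool, bool],
    indirect: float,
    gamma_prime: float,
    total: float,
) -> str:
    c1, c2, c3, c4 = criteria
    signs_oppose = indirect * gamma_prime < 0
    if c1 and c2 and c4 and signs_oppose and abs(gamma_prime) > abs(total):
        return "suppression"
    if c1 and c2 and c3 and c4 and abs(gamma_prime) < abs(total):
        return "mediation"
    return "none"


def mediation_from_estimates(
    alpha: float,
    se_alpha: float,
    p_alpha: float,
    beta: float,
    se_beta: float,
    p_beta: float,
    gamma_prime: float,
    se_gamma_prime: float = float("nan"),
    p_gamma_prime: float = float("nan"),
    p_total: float | None = None,
    se_total: float = float("nan"),
    alpha_level: float = 0.05,
    aroian: bool = False,
) -> MediationResult:
    """Assemble a mediation result from already-fitted path estimates.

    Useful for auditing a published mediation table: the derived quantities
    (indirect effect, total effect, Sobel SE/z/p, criterion flags and the
    classification) are recomputed from the reported coefficients.
    """
    indirect = alpha * beta
    se_ind = sobel_se(alpha, se_alpha, beta, se_beta, aroian=aroian)
    total = indirect + gamma_prime
    z = indirect / se_ind
    sobel_p = 2.0 * stats.norm.sf(abs(z))
    if p_total is None:
        p_total = float("nan")
    criteria = (
        bool(p_alpha < alpha_level),
        bool(p_beta < alpha_level),
        bool(p_total < alpha_level),
        bool(sobel_p < alpha_level),
    )
    return MediationResult(
        alpha=alpha,
        se_alpha=se_alpha,
        p_alpha=p_alpha,
        beta=beta,
        se_beta=se_beta,
        p_beta=p_beta,
        gamma_prime=gamma_prime,
        se_gamma_prime=se_gamma_prime,
        p_gamma_prime=p_gamma_prime,
        indirect=indirect,
        se_indirect=se_ind,
        total=total,
        p_total=float(p_total),
        sobel_z=z,
        sobel_p=float(sobel_p),
        criteria=criteria,
        classification=_classify(criteria, indirect, gamma_prime, total),
        se_total=se_total,
    )


def _complete_cases(
    cohort: CohortTable,
    exposure: np.ndarray,
    covariates: tuple[str, ...],
) -> tuple[CohortTable, np.ndarray]:
    df = cohort.data
    cols = ["tg", "hdl", *covariates]
    mask = np.isfinite(np.asarray(exposure, dtype=float))
    for c in cols:
        mask &= df[c].notna().to_numpy()
    sub = CohortTable(df.loc[mask].reset_index(drop=True))
    return sub, np.asarray(exposure, dtype=float)[mask]


def run_mediation(
    cohort: CohortTable,
    exposure: np.ndarray,
    mediator: str = "tg",
    outcome: str = "hdl",
    alpha_level: float = 0.05,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    aroian: bool = False,
    log_base: float = math.e,
) -> MediationResult:
    """Run the four-criterion mediation analysis on a cohort.

    Fits the three covariate-adjusted path models on the complete-case
    subset (listwise deletion across every model variable, so the identity
    total = alpha * beta + gamma' holds exactly against the independently
    fitted total-effect model), computes the Sobel test of the indirect
    effect, and classifies the configuration as mediation, suppression or
    neither.
    """
    if mediator == outcome:
        raise ValueError("mediator and outcome must differ")
    if mediator != "tg" or outcome != "hdl":
        raise ValueError("this pipeline mediates log TG on the log HDL-C outcome")
    exposure = np.asarray(exposure, dtype=float)
    if np.nanstd(exposure) == 0:
        raise CollinearityError("degenerate (constant) exposure")
    sub, expo = _complete_cases(cohort, exposure, covariates)
    if len(sub) < len(covariates) + 3:
        raise ValueError("too few complete cases for mediation")

    m1 = fit_lipid_model(sub, expo, "tg", covariates=covariates, log_base=log_base)
    m2 = fit_lipid_model(
        sub, expo, "hdl", adjust_tg=True, covariates=covariates, log_base=log_base
    )
    m3 = fit_lipid_model(sub, expo, "hdl", covariates=covariates, log_base=log_base)

    alpha, se_a, p_a = m1["dosage"]
    gamma, se_g, p_g = m2["dosage"]
    beta, se_b, p_b = m2["log_tg"]
    total_fitted, se_t, p_t = m3["dosage"]

    result = mediation_from_estimates(
        alpha=alpha,
        se_alpha=se_a,
        p_alpha=p_a,
        beta=beta,
        se_beta=se_b,
        p_beta=p_b,
        gamma_prime=gamma,
        se_gamma_prime=se_g,
        p_gamma_prime=p_g,
        p_total=p_t,
        se_total=se_t,
        alpha_level=alpha_level,
        aroian=aroian,
    )
    result.n_used = m1.n_used
    result.total_fitted = total_fitted
    return result


def bootstrap_indirect_ci(
    cohort: CohortTable,
    exposure: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
    ci: float = 0.95,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    log_base: float = math.e,
) -> tuple[float, float]:
    """Seeded nonparametric percentile CI for the indirect effect alpha*beta.

    Individuals are resampled with replacement; each replicate refits the
    two path models by least squares (coefficients only).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    sub, expo = _complete_cases(cohort, exposure, covariates)
    df = sub.data
    base = log_base
    log_tg = np.log(df["tg"].to_numpy()) / np.log(base)
    log_hdl = np.log(df["hdl"].to_numpy()) / np.log(base)
    C = df.loc[:, list(covariates)].to_numpy(dtype=float)
    n = len(df)
    ones = np.ones((n, 1))
    X1 = np.hstack([ones, expo[:, None], C])
    X2 = np.hstack([ones, expo[:, None], log_tg[:, None], C])
    rng = np.random.default_rng(seed)
    indirects = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        a = np.linalg.lstsq(X1[idx], log_tg[idx], rcond=None)[0][1]
        bcoef = np.linalg.lstsq(X2[idx], log_hdl[idx], rcond=None)[0][2]
        indirects[b] = a * bcoef
    lo, hi = np.quantile(indirects, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return float(lo), float(hi)
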