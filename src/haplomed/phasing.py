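"""EM haplotype phasing, linkage disequilibrium, and Hardy-Weinberg tests.

Haplotype frequencies over a small SNP window are estimated from unphased
genotypes by expectation-maximization under the assumption of random union of
gametes (Hardy-Weinberg pairing).  The E-step enumerates every ordered
diplotype consistent with an individual's non-missing genotypes (missing
sites are marginalized over both alleles) and weights it by the product of
the current haplotype frequencies; the M-step sets each frequency to its
expected gamete count over 2n.  Individuals sharing a genotype pattern are
grouped, so each iteration costs O(patterns x compatible pairs) rather than
O(n).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import MonomorphicSNPError
from .genotypes import GenotypeMatrix

__all__ = [
    "HaplotypeModel",
    "LdStats",
    "em_phase",
    "filter_haplotypes",
    "best_guess_diplotype",
    "ld_pairwise",
    "hwe_test",
]


@dataclass
class HaplotypeModel:
    """Fitted haplotype frequency model for one SNP window.

    ``haplotypes`` are allele strings sorted by descending frequency and
    labelled H1, H2, ... in that order.  ``dosage`` holds the expected
    (posterior-weighted) copy number of each haplotype per individual;
    ``diplotype_posterior`` maps each individual's unordered haplotype pairs
    to posterior probabilities.
    """

    haplotypes: list[str]
    freqs: np.ndarray
    loglik_trace: np.ndarray
    diplotype_posterior: list[dict[tuple[str, str], float]]
    dosage: np.ndarray
    labels: list[str] = field(default_factory=list)
    dropped_mass: float = 0.0
    n_iter: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if not self.labels:
            self.labels = [f"H{i + 1}" for i in range(len(self.haplotypes))]
        total = self.freqs.sum() + self.dropped_mass
        if abs(total - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies (plus dropped mass) must sum to 1")
        if (self.freqs < -1e-12).any():
            raise ValueError("haplotype frequencies must be non-negative")

    def freq_of(self, haplotype: str) -> float:
        try:
            return float(self.freqs[self.haplotypes.index(haplotype)])
        except ValueError:
            return 0.0

    def dosage_of(self, haplotype: str) -> np.ndarray:
        return self.dosage[:, self.haplotypes.index(haplotype)]


@dataclass
class LdStats:
    """Pairwise linkage disequilibrium between two biallelic SNPs."""

    snp_pair: tuple[str, str]
    d: float
    d_prime: float
    r2: float

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r2 <= 1 + 1e-9 and -1e-9 <= self.d_prime <= 1 + 1e-9):
            raise ValueError("r2 and D' must lie in [0, 1]")


def _enumerate_haplotypes(alleles: list[tuple[str, str]]) -> tuple[np.ndarray, list[str]]:
    """All 2^k haplotypes as alt-indicator rows plus their allele strings."""
    k = len(alleles)
    bits = np.array(
        [[(h >> (k - 1 - s)) & 1 for s in range(k)] for h in range(2**k)], dtype=np.int8
    )
    strings = [
        "".join(alleles[s][bits[h, s]] for s in range(k)) for h in range(2**k)
    ]
    return bits, strings


def em_phase(
    genotypes: GenotypeMatrix,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> HaplotypeModel:
    """Estimate haplotype frequencies from unphased genotypes by EM.

    Frequencies are initialized at the product of marginal allele
    frequencies (deterministic); iteration stops when the largest absolute
    frequency change falls below ``tol`` or after ``max_iter`` iterations.
    Individuals with all calls missing contribute nothing to the likelihood;
    their posteriors reduce to Hardy-Weinberg diplotype priors.

    Raises ``ValueError`` for an empty window or if every call is missing.
    """
    k = genotypes.n_snps
    if k == 0:
        raise ValueError("empty SNP window")
    if k > 16:
        raise ValueError("window too large for exhaustive haplotype enumeration")
    calls = genotypes.calls
    n = calls.shape[0]
    obs = np.where(np.isnan(calls), -1, calls).astype(np.int8)
    informative = (obs >= 0).any(axis=1)
    n_eff = int(informative.sum())
    if n_eff == 0:
        raise ValueError("all genotype calls are missing")

    bits, strings = _enumerate_haplotypes(genotypes.alleles)
    m = bits.shape[0]

    # group individuals by genotype pattern
    patterns, inverse, counts = np.unique(
        obs, axis=0, return_inverse=True, return_counts=True
    )
    # compatible ordered diplotypes per pattern
    pat_pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for g in patterns:
        seen = g >= 0
        if not seen.any():
            idx = np.arange(m)
            I = np.repeat(idx, m)
            J = np.tile(idx, m)
        else:
            sub = bits[:, seen]
            lookup: dict[bytes, list[int]] = {}
            for j in range(m):
                lookup.setdefault(sub[j].tobytes(), []).append(j)
            I_list, J_list = [], []
            target_base = g[seen]
            for i in range(m):
                target = (target_base - sub[i]).astype(np.int8)
                js = lookup.get(target.tobytes())
                if js:
                    I_list.extend([i] * len(js))
                    J_list.extend(js)
            I = np.array(I_list, dtype=np.int64)
            J = np.array(J_list, dtype=np.int64)
        pat_pairs.append((I, J))

    # deterministic init: product of marginal alt frequencies
    with np.errstate(invalid="ignore"):
        p_alt = genotypes.alt_freq()
    p_alt = np.where(np.isfinite(p_alt), p_alt, 0.5)
    f = np.prod(np.where(bits == 1, p_alt, 1.0 - p_alt), axis=1)
    f = f / f.sum()

    # weight of each pattern in the M-step (all-missing patterns carry none)
    pat_info = (patterns >= 0).any(axis=1)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        counts_exp = np.zeros(m)
        ll = 0.0
        for p_idx, (I, J) in enumerate(pat_pairs):
            if not pat_info[p_idx]:
                continue
            w = f[I] * f[J]
            sw = w.sum()
            c = counts[p_idx]
            if sw <= 0.0:
                w = np.full(len(I), 1.0 / len(I))
                ll += c * -np.inf
            else:
                w = w / sw
                ll += c * math.log(sw)
            counts_exp += c * (
                np.bincount(I, weights=w, minlength=m)
                + np.bincount(J, weights=w, minlength=m)
            )
        trace.append(ll)
        f_new = counts_exp / (2.0 * n_eff)
        delta = float(np.abs(f_new - f).max())
        f = f_new
        if delta < tol:
            converged = True
            break

    # final responsibilities under converged frequencies
    pat_posterior: list[dict[tuple[str, str], float]] = []
    pat_dosage = np.zeros((len(patterns), m))
    for p_idx, (I, J) in enumerate(pat_pairs):
        w = f[I] * f[J]
        sw = w.sum()
        w = w / sw if sw > 0 else np.full(len(I), 1.0 / len(I))
        post: dict[tuple[str, str], float] = {}
        for i, j, wi in zip(I, J, w):
            key = (strings[i], strings[j]) if strings[i] <= strings[j] else (strings[j], strings[i])
            post[key] = post.get(key, 0.0) + wi
        pat_posterior.append(post)
        pat_dosage[p_idx] = np.bincount(I, weights=w, minlength=m) + np.bincount(
            J, weights=w, minlength=m
        )

    posterior = [pat_posterior[p] for p in inverse]
    dosage_full = pat_dosage[inverse]

    # keep supported haplotypes, sorted by descending frequency
    keep = np.flatnonzero(f > 1e-10)
    order = sorted(keep, key=lambda h: (-f[h], strings[h]))
    haplotypes = [strings[h] for h in order]
    freqs = f[order]
    freqs = freqs / freqs.sum()
    dosage = dosage_full[:, order]
    # restrict posteriors/dosages to supported pairs and renormalize the
    # negligible mass lost with the dropped zero-frequency haplotypes
    supported = set(haplotypes)
    restricted = []
    for d in posterior:
        sub = {
            pair: p for pair, p in d.items()
            if pair[0] in supported and pair[1] in supported
        }
        total = sum(sub.values())
        restricted.append({pair: p / total for pair, p in sub.items()})
    posterior = restricted
    dosage = dosage * (2.0 / dosage.sum(axis=1, keepdims=True))
    return HaplotypeModel(
        haplotypes=haplotypes,
        freqs=freqs,
        loglik_trace=np.asarray(trace),
        diplotype_posterior=posterior,
        dosage=dosage,
        n_iter=it,
        converged=converged,
    )


def filter_haplotypes(model: HaplotypeModel, min_freq: float = 0.01) -> HaplotypeModel:
    """Drop haplotypes with cohort frequency <= ``min_freq`` from reporting.

    Dosages and posteriors of the dropped haplotypes are removed from the
    reported columns, but the dropped probability mass is recorded so the
    retained frequencies still account for the full distribution.
    """
    keep = np.flatnonzero(model.freqs > min_freq)
    if len(keep) == len(model.haplotypes):
        return model
    dropped = float(model.freqs.sum() - model.freqs[keep].sum())
    retained = {model.haplotypes[i] for i in keep}
    return HaplotypeModel(
        haplotypes=[model.haplotypes[i] for i in keep],
        freqs=model.freqs[keep],
        loglik_trace=model.loglik_trace,
        diplotype_posterior=[
            {p: w for p, w in d.items() if p[0] in retained and p[1] in retained}
            for d in model.diplotype_posterior
        ],
        dosage=model.dosage[:, keep],
        labels=[model.labels[i] for i in keep],
        dropped_mass=model.dropped_mass + dropped,
        n_iter=model.n_iter,
        converged=model.converged,
    )


def best_guess_diplotype(model: HaplotypeModel) -> list[tuple[str, str]]:
    """Hard-assign each individual the maximum-posterior unordered pair.

    Ties (within 1e-12) are broken by lexicographic order of the pair.
    """
    out = []
    for post in model.diplotype_posterior:
        if not post:
            out.append(("", ""))
            continue
        best_p = max(post.values())
        candidates = [pair for pair, p in post.items() if p >= best_p - 1e-12]
        out.append(min(candidates))
    return out


def _ld_from_freqs(p_ab: float, p_a: float, p_b: float) -> tuple[float, float, float]:
    """D, D' and r^2 from the alt-alt haplotype frequency and allele freqs."""
    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = d * d / denom
    return d, d_prime, r2


def ld_pairwise(genotypes: GenotypeMatrix, snp_a: str, snp_b: str) -> LdStats:
    """Pairwise D, D' and r^2 via a two-SNP EM haplotype fit.

    Raises :class:`MonomorphicSNPError` if either SNP has no variation among
    non-missing calls (the statistics are undefined).
    """
    genotypes.require_polymorphic(snp_a)
    genotypes.require_polymorphic(snp_b)
    sub = genotypes.subset(snp_ids=[snp_a, snp_b])
    model = em_phase(sub, tol=1e-12, max_iter=2000)
    alt_a, alt_b = sub.alleles[0][1], sub.alleles[1][1]
    p_ab = sum(
        f for h, f in zip(model.haplotypes, model.freqs) if h[0] == alt_a and h[1] == alt_b
    )
    p_a = sum(f for h, f in zip(model.haplotypes, model.freqs) if h[0] == alt_a)
    p_b = sum(f for h, f in zip(model.haplotypes, model.freqs) if h[1] == alt_b)
    d, d_prime, r2 = _ld_from_freqs(p_ab, p_a, p_b)
    return LdStats(snp_pair=(snp_a, snp_b), d=d, d_prime=d_prime, r2=r2)


def hwe_test(genotypes: GenotypeMatrix, snp: str, method: str = "chisq") -> float:
    """Hardy-Weinberg equilibrium test p-value for one SNP.

    ``method='chisq'`` is the 1-df goodness-of-fit test of observed genotype
    counts against expectations from the allele frequency; ``method='exact'``
    is the conditional exact test that sums the probabilities of heterozygote
    counts no more likely than the observed one.  Monomorphic SNPs return
    p = 1 by convention.
    """
    j = genotypes.snp_index(snp)
    col = genotypes.calls[:, j]
    col = col[~np.isnan(col)]
    if col.size == 0:
        raise ValueError(f"no non-missing calls at {snp}")
    n0 = int((col == 0).sum())
    n1 = int((col == 1).sum())
    n2 = int((col == 2).sum())
    n = n0 + n1 + n2
    p = (n1 + 2 * n2) / (2 * n)
    if p <= 0.0 or p >= 1.0:
        return 1.0
    if method == "chisq":
        expected = np.array([n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p * p])
        observed = np.array([n0, n1, n2], dtype=float)
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        return float(stats.chi2.sf(chi2, df=1))
    if method == "exact":
        return _hwe_exact(n1, n0, n2)
    raise ValueError(f"unknown HWE method: {method}")


def _hwe_exact(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Conditional exact HWE test on the heterozygote count."""
    n = n_het + n_hom_ref + n_hom_alt
    n_rare = n_het + 2 * min(n_hom_ref, n_hom_alt)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    from scipy.special import gammaln

    def _logprob(h):
        hom_rare = (n_rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            h * math.log(2)
            + gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(hom_rare + 1)
            - gammaln(hom_common + 1)
            + gammaln(n_rare + 1)
            + gammaln(2 * n - n_rare + 1)
            - gammaln(2 * n + 1)
        )

    logps = np.array([_logprob(int(h)) for h in hets])
    probs = np.exp(logps - logps.max())
    probs = probs / probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())
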