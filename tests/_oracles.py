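"""Independent reference implementations used only as test oracles.

These deliberately use naive exhaustive enumeration / direct linear algebra,
not the package's own code paths.
"""
from __future__ import annotations

import numpy as np
from scipy import stats


def brute_force_diplotype_posteriors(genotypes, haplotypes, freqs):
    """Posterior over unordered diplotypes, enumerated exhaustively.

    For each individual, every ordered pair of the supplied haplotypes is
    checked for consistency with the non-missing genotype calls (allele
    counts of the alt allele); consistent pairs are weighted by the product
    of haplotype frequencies and normalized.
    """
    freqs = np.asarray(freqs, dtype=float)
    k = genotypes.n_snps
    alt = [a[1] for a in genotypes.alleles]
    hap_alt = np.array(
        [[1 if h[s] == alt[s] else 0 for s in range(k)] for h in haplotypes]
    )
    out = []
    for row in genotypes.calls:
        seen = ~np.isnan(row)
        post = {}
        for i, h1 in enumerate(haplotypes):
            for j, h2 in enumerate(haplotypes):
                counts = hap_alt[i] + hap_alt[j]
                if np.all(counts[seen] == row[seen]):
                    key = (h1, h2) if h1 <= h2 else (h2, h1)
                    post[key] = post.get(key, 0.0) + freqs[i] * freqs[j]
        total = sum(post.values())
        out.append({p: w / total for p, w in post.items()} if total > 0 else {})
    return out


def ols_normal_equations(y, X):
    """OLS coefficients, SEs and two-sided t p-values by direct solve."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - p)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(xtx)))
    t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), df=n - p)
    return beta, se, pvals


def ld_from_gamete_counts(n_ab, n_aB, n_Ab, n_AB):
    """D, D' and r^2 from a fully phased 2x2 gamete table.

    Upper-case letters denote the alt allele at each SNP.
    """
    n = n_ab + n_aB + n_Ab + n_AB
    p_ab_alt = n_AB / n
    p_a = (n_AB + n_Ab) / n
    p_b = (n_AB + n_aB) / n
    d = p_ab_alt - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return d, (abs(d) / d_max if d_max > 0 else 0.0), r2
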