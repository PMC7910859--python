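"""Unphased genotype matrix container.

Genotypes are stored as alt-allele counts (0, 1, 2) in a dense float array,
with ``numpy.nan`` marking missing calls.  This mirrors the dosage coding of
the additive genetic model used throughout the pipeline.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import MonomorphicSNPError

__all__ = ["GenotypeMatrix"]


@dataclass
class GenotypeMatrix:
    """Per-individual unphased allele counts at biallelic SNPs.

    Parameters
    ----------
    snp_ids
        Ordered, unique SNP identifiers.
    alleles
        Per-SNP ``(ref, alt)`` character pair.  Calls count the alt allele.
    calls
        ``(n_samples, n_snps)`` float array with values in {0, 1, 2, nan}.
    sample_ids
        Ordered, unique sample identifiers.
    chrom, pos
        Optional per-SNP chromosome labels and base-pair positions.
    """

    snp_ids: list[str]
    alleles: list[tuple[str, str]]
    calls: np.ndarray
    sample_ids: list[str]
    chrom: list[str] | None = None
    pos: list[int] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        n, k = self.calls.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != k:
            raise ValueError("ids do not match calls shape")
        if len(self.alleles) != k:
            raise ValueError("alleles must give one (ref, alt) pair per SNP")
        if len(set(self.snp_ids)) != k:
            raise ValueError("snp_ids must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        finite = self.calls[~np.isnan(self.calls)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("calls must be 0, 1, 2 or nan")
        if self.chrom is not None and len(self.chrom) != k:
            raise ValueError("chrom must have one entry per SNP")
        if self.pos is not None and len(self.pos) != k:
            raise ValueError("pos must have one entry per SNP")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP id: {snp_id}") from None

    # -- per-SNP summary statistics ---------------------------------------
    def missing_rate(self) -> np.ndarray:
        """Fraction of missing calls per SNP."""
        return np.isnan(self.calls).mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency per SNP among non-missing calls (nan if none)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.calls, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP."""
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def require_polymorphic(self, snp_id: str) -> None:
        p = self.alt_freq()[self.snp_index(snp_id)]
        if not np.isfinite(p) or p <= 0.0 or p >= 1.0:
            raise MonomorphicSNPError(
                f"SNP {snp_id} is monomorphic among non-missing calls"
            )

    # -- subsetting --------------------------------------------------------
    def subset(
        self,
        snp_ids: list[str] | None = None,
        sample_ids: list[str] | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given SNPs and/or samples."""
        cols = (
            [self.snp_index(s) for s in snp_ids]
            if snp_ids is not None
            else list(range(self.n_snps))
        )
        if sample_ids is not None:
            lookup = {s: i for i, s in enumerate(self.sample_ids)}
            rows = [lookup[s] for s in sample_ids]
        else:
            rows = list(range(self.n_samples))
        return GenotypeMatrix(
            snp_ids=[self.snp_ids[j] for j in cols],
            alleles=[self.alleles[j] for j in cols],
            calls=self.calls[np.ix_(rows, cols)].copy(),
            sample_ids=[self.sample_ids[i] for i in rows],
            chrom=[self.chrom[j] for j in cols] if self.chrom is not None else None,
            pos=[self.pos[j] for j in cols] if self.pos is not None else None,
        )
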