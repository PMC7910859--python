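"""Reading and writing of genotype and phenotype files.

Genotypes travel as uncompressed VCF v4.2 (unphased ``/`` genotypes) or as a
rectangular TSV of allele-count codes; phenotypes/covariates as a TSV with one
header row.  VCF parsing is delegated to :mod:`cyvcf2`.
"""
from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_phenotypes",
    "write_phenotypes",
    "load_yaml_config",
]

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write an unphased VCF v4.2 with a single GT FORMAT field."""
    chrom = genotypes.chrom or ["1"] * genotypes.n_snps
    pos = genotypes.pos or list(range(1, genotypes.n_snps + 1))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haplomed\n")
        for c in dict.fromkeys(str(c) for c in chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
        fh.write("\t".join(header[:7] + ["INFO", "FORMAT"] + list(genotypes.sample_ids)) + "\n")
        for j in range(genotypes.n_snps):
            ref, alt = genotypes.alleles[j]
            fields = [
                str(chrom[j]),
                str(pos[j]),
                genotypes.snp_ids[j],
                ref,
                alt,
                ".",
                "PASS",
                ".",
                "GT",
            ]
            col = genotypes.calls[:, j]
            gts = ["./." if np.isnan(g) else _GT_STRINGS[int(g)] for g in col]
            fh.write("\t".join(fields + gts) + "\n")


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a (possibly gzipped) VCF into a :class:`GenotypeMatrix`."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snp_ids, alleles, chrom, pos, rows = [], [], [], [], []
    for i, variant in enumerate(vcf):
        snp_ids.append(variant.ID or f"snp{i + 1}")
        alt = variant.ALT[0] if variant.ALT else "N"
        alleles.append((variant.REF, alt))
        chrom.append(str(variant.CHROM))
        pos.append(int(variant.POS))
        row = np.full(len(sample_ids), np.nan)
        for s, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            if a >= 0 and b >= 0:
                row[s] = a + b
        rows.append(row)
    vcf.close()
    calls = np.asarray(rows).T if rows else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(
        snp_ids=snp_ids,
        alleles=alleles,
        calls=calls,
        sample_ids=sample_ids,
        chrom=chrom or None,
        pos=pos or None,
    )


def write_genotype_tsv(genotypes: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write allele-count codes as a samples x SNPs TSV (NA for missing)."""
    df = pd.DataFrame(
        genotypes.calls, index=genotypes.sample_ids, columns=genotypes.snp_ids
    )
    df = df.map(lambda g: "NA" if np.isnan(g) else str(int(g)))
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def read_genotype_tsv(
    path: str | os.PathLike,
    alleles: list[tuple[str, str]] | None = None,
) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="id", na_values=["NA"])
    if alleles is None:
        alleles = [("A", "B")] * df.shape[1]
    return GenotypeMatrix(
        snp_ids=[str(c) for c in df.columns],
        alleles=alleles,
        calls=df.to_numpy(dtype=float),
        sample_ids=[str(i) for i in df.index],
    )


PHENOTYPE_COLUMNS = ["id", "age", "sex", "bmi", "smoking", "tg", "hdl", "tc", "ldl"]


def write_phenotypes(data: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the phenotype/covariate table with the canonical column order."""
    cols = [c for c in PHENOTYPE_COLUMNS if c in data.columns]
    cols += [c for c in data.columns if c not in cols]
    data.loc[:, cols].to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def load_yaml_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
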