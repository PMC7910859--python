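"""End-to-end pipeline stages with configuration, provenance and TSV outputs.

Each stage is a plain function taking a :class:`PipelineConfig`; the command
line interface in :mod:`haplomed.cli` is a thin wrapper around these.  Every
run writes a provenance JSON next to its outputs (config hash, seed, package
version, row counts at each filter) and is deterministic given the seed.
"""
from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from . import io as hio
from .association import (
    CohortTable,
    cohort_summary,
    haplotype_association_table,
    qc_filter,
    snp_scan,
)
from .mediation import run_mediation
from .phasing import em_phase, filter_haplotypes
from .simulate import SimulationConfig, simulate_cohort, write_cohort

__all__ = ["PipelineConfig", "cmd_simulate", "cmd_phase", "cmd_assoc",
           "cmd_scan", "cmd_mediate", "cmd_all"]

FOCAL_SNP_IDS = ["rs1077834", "rs1800588", "rs2070895"]


@dataclass
class PipelineConfig:
    """Configuration shared by all pipeline commands."""

    out_dir: str = "haplomed_out"
    seed: int = 1
    genotypes_vcf: str | None = None
    phenotypes_tsv: str | None = None
    focal_snps: list[str] = field(default_factory=lambda: list(FOCAL_SNP_IDS))
    covariates: list[str] = field(default_factory=lambda: ["age", "sex", "bmi", "smoking"])
    log_base: float = math.e
    maf_min: float = 0.05
    missing_max: float = 0.03
    hwe_p_min: float = 1e-6
    min_hap_freq: float = 0.01
    em_tol: float = 1e-8
    em_max_iter: int = 1000
    alpha_level: float = 0.05
    scan_threshold: float = 5e-8
    adjust_tg: bool = True
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min <= 0.5 and 0 <= self.missing_max <= 1):
            raise ValueError("QC thresholds out of range")
        if not 0 <= self.hwe_p_min <= 1:
            raise ValueError("hwe_p_min must be a probability")
        if not 0 < self.alpha_level < 1:
            raise ValueError("alpha_level must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        raw = hio.load_yaml_config(path)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if raw.get("log_base") in (None, "e", "natural"):
            raw["log_base"] = math.e
        return cls(**raw)

    def simulation_config(self) -> SimulationConfig:
        params = dict(self.simulate)
        params.setdefault("seed", self.seed)
        params.setdefault("log_base", self.log_base)
        if "intercepts" in params:
            params["intercepts"] = tuple(params["intercepts"])
        if "covariate_effects" in params:
            params["covariate_effects"] = {
                k: tuple(v) for k, v in params["covariate_effects"].items()
            }
        return SimulationConfig(**params)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_provenance(cfg: PipelineConfig, stage: str, counts: dict) -> str:
    os.makedirs(cfg.out_dir, exist_ok=True)
    path = os.path.join(cfg.out_dir, f"provenance_{stage}.json")
    with open(path, "w") as fh:
        json.dump(
            {
                "stage": stage,
                "config_sha256": cfg.digest(),
                "seed": cfg.seed,
                "haplomed_version": __version__,
                "counts": counts,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return path


def _load_inputs(cfg: PipelineConfig):
    if cfg.genotypes_vcf is None or cfg.phenotypes_tsv is None:
        raise FileNotFoundError(
            "genotypes_vcf and phenotypes_tsv must be set (run 'simulate' first "
            "or point the config at existing files)"
        )
    for path in (cfg.genotypes_vcf, cfg.phenotypes_tsv):
        if not os.path.exists(path):
            raise FileNotFoundError(f"input file not found: {path}")
    genotypes = hio.read_vcf(cfg.genotypes_vcf)
    cohort = CohortTable(hio.read_phenotypes(cfg.phenotypes_tsv))
    geno_set = set(genotypes.sample_ids)
    common = [s for s in cohort.sample_ids if s in geno_set]
    if not common:
        raise ValueError("no overlapping samples between genotypes and phenotypes")
    genotypes = genotypes.subset(sample_ids=common)
    lookup = {s: i for i, s in enumerate(cohort.sample_ids)}
    cohort = CohortTable(cohort.data.iloc[[lookup[s] for s in common]].reset_index(drop=True))
    return genotypes, cohort


def cmd_simulate(cfg: PipelineConfig) -> dict[str, str]:
    """Generate a synthetic cohort and write VCF/TSV/truth files."""
    cohort = simulate_cohort(cfg.simulation_config())
    paths = write_cohort(cohort, os.path.join(cfg.out_dir, "cohort"))
    cfg.genotypes_vcf = paths["vcf"]
    cfg.phenotypes_tsv = paths["phenotypes_tsv"]
    summary = cohort_summary(cohort.cohort)
    summary_path = os.path.join(cfg.out_dir, "cohort_summary.tsv")
    summary.to_csv(summary_path, sep="\t", index=False, float_format="%.6g")
    paths["summary_tsv"] = summary_path
    paths["provenance"] = _write_provenance(
        cfg,
        "simulate",
        {
            "n_individuals": cohort.genotypes.n_samples,
            "n_snps": cohort.genotypes.n_snps,
        },
    )
    return paths


def _phase_focal(cfg: PipelineConfig, genotypes):
    focal = [s for s in cfg.focal_snps if s in genotypes.snp_ids]
    if len(focal) < 2:
        raise ValueError("fewer than two focal SNPs present in the genotypes")
    window = genotypes.subset(snp_ids=focal)
    model = em_phase(window, tol=cfg.em_tol, max_iter=cfg.em_max_iter)
    return filter_haplotypes(model, cfg.min_hap_freq), model


def cmd_phase(cfg: PipelineConfig) -> dict[str, str]:
    """EM-phase the focal SNP window and write the haplotype frequency table."""
    genotypes, _ = _load_inputs(cfg)
    filtered, full = _phase_focal(cfg, genotypes)
    table = pd.DataFrame(
        {
            "haplotype": filtered.labels,
            "alleles": filtered.haplotypes,
            "frequency": filtered.freqs,
        }
    )
    os.makedirs(cfg.out_dir, exist_ok=True)
    out = os.path.join(cfg.out_dir, "haplotype_frequencies.tsv")
    table.to_csv(out, sep="\t", index=False, float_format="%.6g")
    prov = _write_provenance(
        cfg,
        "phase",
        {
            "n_haplotypes_full": len(full.haplotypes),
            "n_haplotypes_retained": len(filtered.haplotypes),
            "dropped_mass": filtered.dropped_mass,
            "em_iterations": full.n_iter,
        },
    )
    return {"haplotype_frequencies_tsv": out, "provenance": prov}


def cmd_assoc(cfg: PipelineConfig) -> dict[str, str]:
    """Per-haplotype lipid association table (TG, HDL, TG-adjusted HDL)."""
    genotypes, cohort = _load_inputs(cfg)
    filtered, _ = _phase_focal(cfg, genotypes)
    table = haplotype_association_table(
        filtered, cohort, covariates=tuple(cfg.covariates), log_base=cfg.log_base
    )
    os.makedirs(cfg.out_dir, exist_ok=True)
    out = os.path.join(cfg.out_dir, "haplotype_association.tsv")
    table.to_csv(out, sep="\t", index=False, float_format="%.6g")
    prov = _write_provenance(
        cfg, "assoc", {"n_haplotypes": len(table), "n_individuals": len(cohort)}
    )
    return {"haplotype_association_tsv": out, "provenance": prov}


def cmd_scan(cfg: PipelineConfig, manhattan: str | None = None) -> dict[str, str]:
    """QC-filter the SNPs and scan log HDL-C per SNP (optionally TG-adjusted)."""
    genotypes, cohort = _load_inputs(cfg)
    n_in = genotypes.n_snps
    filtered, report = qc_filter(
        genotypes,
        maf_min=cfg.maf_min,
        missing_max=cfg.missing_max,
        hwe_p_min=cfg.hwe_p_min,
    )
    result = snp_scan(
        filtered,
        cohort,
        adjust_tg=cfg.adjust_tg,
        threshold=cfg.scan_threshold,
        covariates=tuple(cfg.covariates),
        log_base=cfg.log_base,
    )
    os.makedirs(cfg.out_dir, exist_ok=True)
    out = os.path.join(cfg.out_dir, "snp_scan.tsv")
    result.table.to_csv(out, sep="\t", index=False, float_format="%.6g")
    qc_out = os.path.join(cfg.out_dir, "qc_report.tsv")
    report.to_csv(qc_out, sep="\t", index=False, float_format="%.6g")
    outputs = {"snp_scan_tsv": out, "qc_report_tsv": qc_out}
    if manhattan:
        _manhattan_plot(result, manhattan)
        outputs["manhattan_png"] = manhattan
    outputs["provenance"] = _write_provenance(
        cfg,
        "scan",
        {
            "snps_in": n_in,
            "snps_retained": filtered.n_snps,
            "snps_excluded": n_in - filtered.n_snps,
            "hits": int(result.hits.shape[0]),
        },
    )
    return outputs


def _manhattan_plot(result, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table.dropna(subset=["p_value"])
    x = np.arange(len(t))
    y = -np.log10(t["p_value"].to_numpy())
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.scatter(x, y, s=8, c=pd.factorize(t["chrom"])[0] % 2, cmap="tab10")
    ax.axhline(-math.log10(result.threshold), color="red", ls="--", lw=0.8)
    ax.set_xlabel("SNP (genome order)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cmd_mediate(cfg: PipelineConfig) -> dict[str, str]:
    """Mediation/suppression analysis of the most frequent haplotype."""
    genotypes, cohort = _load_inputs(cfg)
    filtered, _ = _phase_focal(cfg, genotypes)
    dose = filtered.dosage[:, 0]  # H1 = most frequent haplotype
    result = run_mediation(
        cohort,
        dose,
        alpha_level=cfg.alpha_level,
        covariates=tuple(cfg.covariates),
        log_base=cfg.log_base,
    )
    frame = result.to_frame()
    frame["haplotype"] = filtered.labels[0]
    os.makedirs(cfg.out_dir, exist_ok=True)
    out = os.path.join(cfg.out_dir, "mediation.tsv")
    with open(out, "w") as fh:
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        fh.write(f"# sobel_z\t{result.sobel_z:.6g}\n")
        fh.write(f"# classification\t{result.classification}\n")
        fh.write(f"# criteria\t{','.join(str(c) for c in result.criteria)}\n")
    prov = _write_provenance(
        cfg, "mediate", {"n_used": result.n_used, "classification": result.classification}
    )
    return {"mediation_tsv": out, "provenance": prov}


def cmd_all(cfg: PipelineConfig, manhattan: str | None = None) -> dict[str, str]:
    """Run simulate -> phase -> assoc -> scan -> mediate in sequence."""
    outputs = {}
    outputs.update(cmd_simulate(cfg))
    outputs.update(cmd_phase(cfg))
    outputs.update(cmd_assoc(cfg))
    outputs.update(cmd_scan(cfg, manhattan=manhattan))
    outputs.update(cmd_mediate(cfg))
    return outputs
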