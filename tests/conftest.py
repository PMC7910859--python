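from __future__ import annotations

import numpy as np
import pytest

from haplomed import SimulationConfig, simulate_cohort
from haplomed.genotypes import GenotypeMatrix


@pytest.fixture(scope="session")
def default_cohort():
    """Medium-sized cohort under the default suppression configuration."""
    return simulate_cohort(SimulationConfig(n_individuals=2000, seed=20210122))


@pytest.fixture(scope="session")
def large_cohort():
    """Full-size cohort (n = 4000) under the default configuration."""
    return simulate_cohort(SimulationConfig(n_individuals=4000, seed=148))


def genotype_matrix_from_calls(calls, alleles=None, snp_ids=None, **kwargs):
    """Build a small GenotypeMatrix from a nested list of allele counts."""
    calls = np.asarray(calls, dtype=float)
    n, k = calls.shape
    if alleles is None:
        alleles = [("A", "B")] * k
    if snp_ids is None:
        snp_ids = [f"snp{j + 1}" for j in range(k)]
    return GenotypeMatrix(
        snp_ids=snp_ids,
        alleles=alleles,
        calls=calls,
        sample_ids=[f"s{i + 1}" for i in range(n)],
        **kwargs,
    )
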