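"""Tests of EM phasing, LD statistics and Hardy-Weinberg tests."""
from __future__ import annotations

import numpy as np
import pytest

from _oracles import brute_force_diplotype_posteriors, ld_from_gamete_counts
from conftest import genotype_matrix_from_calls

from haplomed import (
    SimulationConfig,
    best_guess_diplotype,
    em_phase,
    filter_haplotypes,
    hwe_test,
    ld_pairwise,
    simulate_cohort,
)
from haplomed.exceptions import MonomorphicSNPError
from haplomed.phasing import HaplotypeModel
from haplomed.simulate import DEFAULT_HAPLOTYPE_FREQS


# ---------------------------------------------------------------- EM core
def test_all_homozygous_equals_direct_counting():
    """With no heterozygotes EM reduces to counting gametes directly."""
    geno = genotype_matrix_from_calls(
        [[0, 0, 0]] * 3,
        alleles=[("T", "C"), ("C", "T"), ("G", "A")],
    )
    model = em_phase(geno)
    assert model.haplotypes == ["TCG"]
    assert model.freqs[0] == pytest.approx(1.0)
    assert all(post == {("TCG", "TCG"): pytest.approx(1.0)} for post in model.diplotype_posterior)


def test_two_snp_unambiguous_half_half():
    geno = genotype_matrix_from_calls([[0, 0], [0, 0], [2, 2], [2, 2]])
    model = em_phase(geno)
    freqs = dict(zip(model.haplotypes, model.freqs))
    assert freqs == {"AA": pytest.approx(0.5), "BB": pytest.approx(0.5)}
    trace = model.loglik_trace
    assert (np.diff(trace) >= -1e-9).all()


def test_em_recovers_simulated_frequencies():
    cohort = simulate_cohort(SimulationConfig(n_individuals=500, seed=42))
    model = em_phase(cohort.genotypes)
    n_gametes = 2 * 500
    for hap, f in DEFAULT_HAPLOTYPE_FREQS.items():
        if f < 0.01:
            continue
        sd = np.sqrt(f * (1 - f) / n_gametes)
        assert abs(model.freq_of(hap) - f) < 4 * sd


@pytest.mark.parametrize("missing_rate", [0.0, 0.15])
@pytest.mark.parametrize("n_snps_extra", [0, 1])
def test_posteriors_match_brute_force_enumeration(missing_rate, n_snps_extra):
    """EM posteriors agree with exhaustive diplotype enumeration to 1e-9."""
    cfg = SimulationConfig(
        n_individuals=50,
        seed=13 + n_snps_extra,
        missing_rate=missing_rate,
        n_null_snps=n_snps_extra,
    )
    cohort = simulate_cohort(cfg)
    geno = cohort.genotypes  # 3 or 4 SNP window
    model = em_phase(geno)
    oracle = brute_force_diplotype_posteriors(geno, model.haplotypes, model.freqs)
    for em_post, ref_post in zip(model.diplotype_posterior, oracle):
        assert set(em_post) == set(ref_post)
        for pair, p in ref_post.items():
            assert em_post[pair] == pytest.approx(p, abs=1e-9)


def test_em_model_invariants(default_cohort):
    model = em_phase(default_cohort.genotypes)
    assert model.converged
    assert model.freqs.sum() == pytest.approx(1.0, abs=1e-9)
    assert (np.diff(model.loglik_trace) >= -1e-9).all()
    np.testing.assert_allclose(model.dosage.sum(axis=1), 2.0, atol=1e-9)
    for post in model.diplotype_posterior:
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)
    # EM stationarity: mean dosage of each haplotype equals 2 * frequency
    np.testing.assert_allclose(model.dosage.mean(axis=0), 2 * model.freqs, atol=1e-7)
    # labels follow descending frequency
    assert model.labels[: 3] == ["H1", "H2", "H3"]
    assert (np.diff(model.freqs) <= 1e-12).all()


def test_em_marginalizes_missing_sites():
    cohort = simulate_cohort(
        SimulationConfig(n_individuals=800, seed=8, missing_rate=0.1)
    )
    model = em_phase(cohort.genotypes)
    assert model.freq_of("TCG") == pytest.approx(0.613, abs=0.06)
    np.testing.assert_allclose(model.dosage.sum(axis=1), 2.0, atol=1e-9)


def test_em_error_cases():
    with pytest.raises(ValueError):
        em_phase(genotype_matrix_from_calls(np.empty((3, 0))))
    geno = genotype_matrix_from_calls([[np.nan, np.nan]] * 4)
    with pytest.raises(ValueError):
        em_phase(geno)


# ----------------------------------------------------- haplotype filtering
def _toy_model(freqs, haps=None):
    freqs = np.asarray(freqs, dtype=float)
    haps = haps or [f"h{i}" for i in range(len(freqs))]
    return HaplotypeModel(
        haplotypes=list(haps),
        freqs=freqs,
        loglik_trace=np.array([-1.0]),
        diplotype_posterior=[{(haps[0], haps[0]): 1.0}],
        dosage=np.tile(2 * freqs, (1, 1)),
    )


def test_filter_drops_rare_haplotypes_and_records_mass():
    model = _toy_model([0.613, 0.361, 0.025, 0.001], ["TCG", "CTA", "CCA", "TTA"])
    out = filter_haplotypes(model, min_freq=0.01)
    assert out.haplotypes == ["TCG", "CTA", "CCA"]
    assert out.freqs.sum() == pytest.approx(0.999, abs=1e-12)
    assert out.dropped_mass == pytest.approx(0.001, abs=1e-12)


@pytest.mark.parametrize("min_freq", [0.0, 0.01])
def test_filter_is_identity_when_nothing_to_drop(min_freq):
    model = _toy_model([0.6, 0.4])
    out = filter_haplotypes(model, min_freq=min_freq)
    assert out is model


# ------------------------------------------------------- hard assignment
def test_best_guess_homozygote_is_certain():
    geno = genotype_matrix_from_calls([[0, 0, 0], [2, 2, 2]],
                                      alleles=[("T", "C"), ("C", "T"), ("G", "A")])
    model = em_phase(geno)
    pairs = best_guess_diplotype(model)
    assert pairs[0] == ("TCG", "TCG")
    assert pairs[1] == ("CTA", "CTA")


def test_best_guess_tie_breaks_lexicographically():
    # double heterozygote with all four 2-SNP haplotypes equally frequent:
    # posterior is split 0.5 / 0.5 between (AA,BB) and (AB,BA)
    calls = [[0, 0], [0, 2], [2, 0], [2, 2], [1, 1], [1, 1]]
    model = em_phase(genotype_matrix_from_calls(calls))
    freqs = dict(zip(model.haplotypes, model.freqs))
    assert all(abs(f - 0.25) < 1e-6 for f in freqs.values())
    pairs = best_guess_diplotype(model)
    assert pairs[4] == ("AA", "BB")  # lexicographically smaller of the tie


def test_best_guess_beats_random_consistent_assignment(default_cohort):
    model = em_phase(default_cohort.genotypes)
    truth = {tuple(sorted(d)) for d in map(tuple, default_cohort.true_diplotypes)}
    truth_pairs = [tuple(sorted(d)) for d in map(tuple, default_cohort.true_diplotypes)]
    best = best_guess_diplotype(model)
    best_acc = np.mean([b == t for b, t in zip(best, truth_pairs)])
    rng = np.random.default_rng(0)
    rand_acc = np.mean(
        [
            list(post)[rng.integers(len(post))] == t
            for post, t in zip(model.diplotype_posterior, truth_pairs)
        ]
    )
    assert best_acc >= rand_acc
    assert best_acc > 0.9  # 3-SNP window has little phase ambiguity


# ----------------------------------------------------------------- LD
def test_ld_perfectly_correlated_snps():
    calls = np.tile([[0], [1], [2], [2], [0]], (4, 2))
    geno = genotype_matrix_from_calls(calls[:5])
    stats = ld_pairwise(geno, "snp1", "snp2")
    assert stats.r2 == pytest.approx(1.0, abs=1e-9)
    assert stats.d_prime == pytest.approx(1.0, abs=1e-9)


def test_ld_independent_snps_near_zero():
    rng = np.random.default_rng(1)
    calls = np.column_stack(
        [rng.binomial(2, 0.4, size=2000), rng.binomial(2, 0.3, size=2000)]
    ).astype(float)
    geno = genotype_matrix_from_calls(calls)
    assert ld_pairwise(geno, "snp1", "snp2").r2 < 0.01


def test_ld_matches_phased_gamete_table_oracle():
    """Homozygotes carry known phase: gamete table AB:40 Ab:10 aB:10 ab:40."""
    calls = (
        [[2, 2]] * 40 + [[2, 0]] * 10 + [[0, 2]] * 10 + [[0, 0]] * 40
    )
    geno = genotype_matrix_from_calls(calls)
    stats = ld_pairwise(geno, "snp1", "snp2")
    d, d_prime, r2 = ld_from_gamete_counts(40, 10, 10, 40)
    assert (d_prime, r2) == (pytest.approx(0.6), pytest.approx(0.36))
    assert stats.r2 == pytest.approx(r2, abs=1e-9)
    assert stats.d_prime == pytest.approx(d_prime, abs=1e-9)
    assert stats.d == pytest.approx(d, abs=1e-9)


def test_ld_monomorphic_snp_raises():
    geno = genotype_matrix_from_calls([[0, 1], [0, 1], [0, 0]])
    with pytest.raises(MonomorphicSNPError):
        ld_pairwise(geno, "snp1", "snp2")


# ----------------------------------------------------------------- HWE
def test_hwe_exact_equilibrium_counts_give_p_one():
    calls = [[0]] * 25 + [[1]] * 50 + [[2]] * 25
    geno = genotype_matrix_from_calls(calls)
    assert hwe_test(geno, "snp1") == pytest.approx(1.0)


def test_hwe_no_heterozygotes_is_extreme():
    """Counts (50, 0, 50): chi-square equals n, far below 1e-6."""
    calls = [[0]] * 50 + [[2]] * 50
    geno = genotype_matrix_from_calls(calls)
    from scipy.stats import chi2

    expected_p = chi2.sf(100, df=1)
    assert hwe_test(geno, "snp1") == pytest.approx(expected_p, rel=1e-9)
    assert hwe_test(geno, "snp1") < 1e-6
    assert hwe_test(geno, "snp1", method="exact") < 1e-6


def test_hwe_monomorphic_returns_one_by_convention():
    geno = genotype_matrix_from_calls([[0], [0], [0]])
    assert hwe_test(geno, "snp1") == 1.0
    assert hwe_test(geno, "snp1", method="exact") == 1.0


@pytest.mark.parametrize("method", ["chisq", "exact"])
def test_hwe_calibration_under_the_null(method):
    """Type-I error at 0.05 stays near nominal over 1000 HWE SNPs."""
    rng = np.random.default_rng(7)
    n, reps = 500, 1000
    rejections = 0
    for _ in range(reps):
        gametes = rng.binomial(1, 0.3, size=(n, 2))
        geno = genotype_matrix_from_calls(gametes.sum(axis=1)[:, None])
        p = hwe_test(geno, "snp1", method=method)
        rejections += p < 0.05
    rate = rejections / reps
    if method == "chisq":
        assert 0.03 <= rate <= 0.07
    else:
        assert rate <= 0.07  # the exact test is conservative
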