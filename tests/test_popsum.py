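"""Single-population SNP-BLUP: centering, precision, θ, solves, summaries."""

import numpy as np
import pytest

from metags.errors import (AlignmentError, DomainError, InvalidFrequencyError,
                           MonomorphicSNPError)
from metags.popsum import (center_genotypes, compute_dgv, compute_theta,
                           recover_rhs, residual_precision, solve_absorbed,
                           solve_single_pop, summarize_population,
                           weighted_center)
from metags.types import GenotypePanel, PhenotypeRecords, PopulationSummary


def _panel(dosage, **kw):
    dosage = np.atleast_2d(dosage)
    m = dosage.shape[1]
    return GenotypePanel(snp_ids=[f"1:s{j}" for j in range(m)],
                         chrom=["1"] * m, dosage=dosage,
                         indiv_ids=[f"i{k}" for k in range(dosage.shape[0])],
                         **kw)


class TestCenterGenotypes:
    @pytest.mark.parametrize("dosage, p, expected", [
        (2, 0.5, 1.0),
        (1, 0.5, 0.0),
        (0, 0.1, -0.2),
    ])
    def test_reference_allele_centering(self, dosage, p, expected):
        Z = center_genotypes(_panel([[dosage]]), np.array([p]))
        assert Z[0, 0] == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_frequency_outside_open_interval_rejected(self, bad):
        with pytest.raises(InvalidFrequencyError):
            center_genotypes(_panel([[1]]), np.array([bad]))


class TestResidualPrecision:
    def test_daughter_counts_over_error_variance(self):
        rec = PhenotypeRecords(y=[0.0, 0.0], n_daughters=[3, 6])
        np.testing.assert_allclose(residual_precision(rec, 3.0), [1.0, 2.0])
        rec1 = PhenotypeRecords(y=[0.0], n_daughters=[10])
        assert residual_precision(rec1, 2.0)[0] == pytest.approx(5.0)

    def test_nonpositive_error_variance_rejected(self):
        rec = PhenotypeRecords(y=[0.0], n_daughters=[1])
        with pytest.raises(DomainError):
            residual_precision(rec, 0.0)

    def test_nonpositive_daughter_count_rejected(self):
        with pytest.raises(DomainError):
            PhenotypeRecords(y=[0.0], n_daughters=[0.0])


class TestTheta:
    @pytest.mark.parametrize("freq, expected", [
        ([0.5], 2.0),
        ([0.5, 0.5], 1.0),
        ([0.1, 0.2], 2.0),
    ])
    def test_heterozygosity_scaling(self, freq, expected):
        assert compute_theta(np.array(freq)).theta == pytest.approx(expected)

    def test_empty_and_fixed_frequencies_rejected(self):
        with pytest.raises(DomainError):
            compute_theta(np.array([]))
        with pytest.raises(InvalidFrequencyError):
            compute_theta(np.array([0.5, 1.0]))


class TestSolveSinglePop:
    def test_null_phenotypes_give_null_solution(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(8, 3))
        mu, g = solve_single_pop(Z, np.full(8, 2.0), np.zeros(8), 1.0, 1.0)
        assert mu == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_matches_hand_solved_two_by_two_system(self):
        # one SNP, two sires: eliminate nothing, solve the full 2x2 by hand
        Z = np.array([[1.0], [-1.0]])
        w = np.array([1.0, 2.0])
        y = np.array([2.0, -1.0])
        # lam = 1/(dgv_var*theta) = 0.5
        mu, g = solve_single_pop(Z, w, y, dgv_var=2.0, theta=1.0)
        A = np.array([[3.0, -1.0], [-1.0, 3.5]])
        b = np.array([0.0, 4.0])
        expected = np.linalg.solve(A, b)
        assert mu == pytest.approx(expected[0])
        assert g[0] == pytest.approx(expected[1])
        assert g[0] == pytest.approx(12.0 / 9.5)

    def test_effects_invariant_to_centering_frequency(self, small_dataset):
        data, _sims = small_dataset
        panel = data.panels[1]
        rng = np.random.default_rng(9)
        w = rng.uniform(1, 5, size=panel.n_indiv)
        y = rng.normal(size=panel.n_indiv)
        theta = compute_theta(panel.allele_freq()).theta
        freq_alt = rng.uniform(0.2, 0.8, size=panel.n_snps)
        _, g1 = solve_single_pop(center_genotypes(panel, panel.allele_freq()),
                                 w, y, 1.0, theta)
        _, g2 = solve_single_pop(center_genotypes(panel, freq_alt),
                                 w, y, 1.0, theta)
        np.testing.assert_allclose(g1, g2, rtol=1e-8, atol=1e-10)


class TestComputeDgv:
    def test_dot_product_and_null_effects(self):
        assert compute_dgv(np.array([[1.0, -1.0]]),
                           np.array([2.0, 3.0]))[0] == pytest.approx(-1.0)
        np.testing.assert_array_equal(
            compute_dgv(np.ones((3, 2)), np.zeros(2)), np.zeros(3))

    def test_matches_elementwise_sum(self):
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(5, 7))
        g = rng.normal(size=7)
        brute = np.array([sum(Z[k, j] * g[j] for j in range(7))
                          for k in range(5)])
        np.testing.assert_allclose(compute_dgv(Z, g), brute)

    def test_dimension_mismatch(self):
        with pytest.raises(AlignmentError):
            compute_dgv(np.ones((2, 3)), np.ones(2))


class TestSummarize:
    def test_hand_computed_one_snp_summary(self):
        panel = _panel([[2], [0]])
        rec = PhenotypeRecords(y=[3.0, 1.0], n_daughters=[2, 4])
        s = summarize_population(panel, rec, err_var=2.0, dgv_var=1.0)
        # freq 0.5, Z=(1,-1), w=(1,2), weighted mean 5/3
        assert s.allele_freq[0] == pytest.approx(0.5)
        assert s.lhs[0, 0] == pytest.approx(3.0)
        assert s.rhs[0] == pytest.approx(8.0 / 3.0)
        # theta=2, lam=0.5: g = (8/3)/3.5
        assert s.effects[0] == pytest.approx(16.0 / 21.0)

    def test_deterministic(self, small_dataset, small_summaries):
        data, sims = small_dataset
        again = summarize_population(data.panels[0], sims[0].records,
                                     err_var=10.0, dgv_var=1.0,
                                     population="pop1")
        np.testing.assert_array_equal(again.lhs, small_summaries[0].lhs)
        np.testing.assert_array_equal(again.effects, small_summaries[0].effects)

    def test_lhs_symmetric_psd(self, small_summaries):
        for s in small_summaries:
            np.testing.assert_allclose(s.lhs, s.lhs.T)
            eig = np.linalg.eigvalsh(s.lhs)
            assert eig[0] >= -1e-8 * eig[-1]

    def test_monomorphic_snp_rejected(self):
        panel = _panel([[2, 1], [2, 0]])
        rec = PhenotypeRecords(y=[1.0, 2.0], n_daughters=[1, 1])
        with pytest.raises(MonomorphicSNPError):
            summarize_population(panel, rec, err_var=1.0, dgv_var=1.0)

    def test_weighted_center_absorbs_mean(self):
        y = np.array([3.0, 1.0, 5.0])
        w = np.array([1.0, 2.0, 1.0])
        yc, ybar = weighted_center(y, w)
        assert ybar == pytest.approx(10.0 / 4.0)
        assert np.dot(w, yc) == pytest.approx(0.0, abs=1e-12)


class TestRecoverRhs:
    def test_round_trip_from_summary(self, small_summaries):
        for s in small_summaries:
            np.testing.assert_allclose(recover_rhs(s), s.rhs,
                                       rtol=1e-8, atol=1e-8)

    def test_null_effects_give_null_rhs(self):
        s = PopulationSummary(snp_ids=["a"], allele_freq=[0.5],
                              lhs=np.eye(1), dgv_var=1.0, err_var=1.0,
                              n_pheno=1, n_geno=1, effects=np.zeros(1))
        assert recover_rhs(s)[0] == 0.0

    def test_identity_case_with_explicit_theta(self):
        s = PopulationSummary(snp_ids=["a"], allele_freq=[0.5],
                              lhs=np.eye(1), dgv_var=1.0, err_var=1.0,
                              n_pheno=1, n_geno=1, effects=np.array([1.0]))
        assert recover_rhs(s, theta=1.0)[0] == pytest.approx(2.0)

    def test_missing_effects_rejected(self):
        s = PopulationSummary(snp_ids=["a"], allele_freq=[0.5],
                              lhs=np.eye(1), dgv_var=1.0, err_var=1.0,
                              n_pheno=1, n_geno=1, rhs=np.array([1.0]))
        with pytest.raises(AlignmentError):
            recover_rhs(s)


def test_shrinkage_vanishes_with_growing_daughter_counts():
    """As residual precision grows the BLUP approaches the least-squares fit."""
    rng = np.random.default_rng(12)
    Z = rng.normal(size=(30, 5))
    y = rng.normal(size=30)
    base_w = rng.uniform(1, 3, size=30)
    yc, _ = weighted_center(y, base_w)  # weights scale cancels in the mean
    lhs0 = Z.T @ (Z * base_w[:, None])
    rhs0 = (Z * base_w[:, None]).T @ yc
    g_ols = np.linalg.solve(lhs0, rhs0)
    dists = []
    for scale in [1.0, 10.0, 100.0, 1e4]:
        g = solve_absorbed(scale * lhs0, scale * rhs0, 1.0, 1.0)
        dists.append(np.linalg.norm(g - g_ols))
    assert all(a > b for a, b in zip(dists, dists[1:]))
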