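"""Rescaling and block-wise summary-statistic imputation via the T matrix."""

import numpy as np
import pytest

from metags.errors import AlignmentError, DomainError, SingularSystemError
from metags.sumstat_ops import (build_T, impute_lhs, impute_rhs,
                                map_solutions, mask_and_evaluate,
                                rescale_and_evaluate, rescale_lhs)
from metags.types import GenotypePanel


def _panel(dosage, chrom=None):
    dosage = np.asarray(dosage)
    m = dosage.shape[1]
    return GenotypePanel(snp_ids=[f"s{j}" for j in range(m)],
                         chrom=chrom if chrom is not None else ["1"] * m,
                         dosage=dosage,
                         indiv_ids=[f"i{k}" for k in range(dosage.shape[0])])


def _random_panel(n, m, seed):
    rng = np.random.default_rng(seed)
    return _panel(rng.integers(0, 3, size=(n, m)))


class TestRescale:
    def test_identity_and_halving(self):
        lhs = np.array([[2.0, 1.0], [1.0, 4.0]])
        np.testing.assert_array_equal(rescale_lhs(lhs, 10, 10), lhs)
        np.testing.assert_allclose(rescale_lhs(lhs, 5, 10), lhs / 2)

    def test_more_phenotypes_than_genotypes_rejected(self):
        with pytest.raises(DomainError):
            rescale_lhs(np.eye(2), 11, 10)

    def test_subset_matrix_tracks_rescaled_full_matrix(self, single_pop_dataset):
        data, sims = single_pop_dataset
        ev = rescale_and_evaluate(data.panels[0], sims[0].records,
                                  err_var=10.0, mask_fraction=0.5,
                                  n_replicates=20, seed=7)
        assert ev.summary.loc["corr", "mean"] > 0.9
        lo, hi = ev.summary.loc["slope", ["ci95_lo", "ci95_hi"]]
        assert lo <= 1.0 <= hi


class TestBuildT:
    def test_no_missing_snps_gives_identity_blocks(self):
        ref = _random_panel(40, 12, seed=1)
        imap = build_T(ref, ref.snp_ids, ref.snp_ids, block_size=5, ridge=0.0)
        widths = [b.width for b in imap.blocks]
        assert widths == [5, 5, 2]
        for b in imap.blocks:
            np.testing.assert_allclose(b.T, np.eye(b.width), atol=1e-9)

    def test_duplicate_snp_column_is_indicator(self):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 3, size=(30, 4))
        dosage = np.column_stack([base, base[:, 1]])  # SNP 4 duplicates SNP 1
        ref = _panel(dosage)
        observed = ref.snp_ids[:4]
        imap = build_T(ref, observed, ref.snp_ids, block_size=10, ridge=0.0)
        col = imap.blocks[0].T[:, 4]
        np.testing.assert_allclose(col, [0, 1, 0, 0], atol=1e-9)

    def test_missing_column_matches_normal_equations(self):
        rng = np.random.default_rng(6)
        ref = _panel(rng.integers(0, 3, size=(60, 8)))
        observed = np.delete(ref.snp_ids, 3)
        imap = build_T(ref, observed, ref.snp_ids, block_size=8, ridge=0.0)
        Z = ref.dosage.astype(float)
        Z = Z - Z.mean(axis=0)
        Zi = np.delete(Z, 3, axis=1)
        expected = np.linalg.solve(Zi.T @ Zi, Zi.T @ Z[:, 3])
        np.testing.assert_allclose(imap.blocks[0].T[:, 3], expected,
                                   rtol=1e-9, atol=1e-10)

    def test_blocks_respect_chromosome_boundaries(self):
        ref = _random_panel(40, 10, seed=8)
        ref = _panel(ref.dosage, chrom=["1"] * 4 + ["2"] * 6)
        imap = build_T(ref, ref.snp_ids, ref.snp_ids, block_size=5)
        assert [(b.start, b.stop) for b in imap.blocks] == [(0, 4), (4, 9), (9, 10)]

    def test_overfull_block_requires_ridge(self):
        ref = _random_panel(10, 30, seed=2)  # more SNPs than individuals
        with pytest.raises(SingularSystemError, match="ridge"):
            build_T(ref, ref.snp_ids[:-1], ref.snp_ids, block_size=30,
                    ridge=0.0)
        imap = build_T(ref, ref.snp_ids[:-1], ref.snp_ids, block_size=30,
                       ridge="auto")
        assert imap.ridge > 0


class TestImpute:
    def test_identity_map_round_trips(self):
        ref = _random_panel(50, 9, seed=4)
        imap = build_T(ref, ref.snp_ids, ref.snp_ids, block_size=4, ridge=0.0)
        rng = np.random.default_rng(0)
        rhs = rng.normal(size=9)
        np.testing.assert_allclose(impute_rhs(imap, rhs), rhs, atol=1e-8)
        A = rng.normal(size=(9, 9))
        lhs = A @ A.T
        np.testing.assert_allclose(impute_lhs(imap, lhs), lhs, atol=1e-7)
        np.testing.assert_allclose(map_solutions(imap, rhs), rhs, atol=1e-8)

    def test_zero_inputs_stay_zero(self):
        ref = _random_panel(50, 6, seed=5)
        imap = build_T(ref, ref.snp_ids[:4], ref.snp_ids, block_size=6,
                       ridge=0.0)
        np.testing.assert_array_equal(impute_rhs(imap, np.zeros(4)), 0.0)
        np.testing.assert_array_equal(map_solutions(imap, np.zeros(6)), 0.0)

    def test_duplicate_snp_statistics_are_copied(self):
        rng = np.random.default_rng(11)
        base = rng.integers(0, 3, size=(40, 5))
        ref = _panel(np.column_stack([base, base[:, 2]]))
        observed = ref.snp_ids[:5]
        imap = build_T(ref, observed, ref.snp_ids, block_size=10, ridge=0.0)
        rhs_obs = rng.normal(size=5)
        rhs_c = impute_rhs(imap, rhs_obs)
        assert rhs_c[5] == pytest.approx(rhs_obs[2])
        A = rng.normal(size=(5, 5))
        lhs_obs = A @ A.T
        lhs_c = impute_lhs(imap, lhs_obs)
        np.testing.assert_allclose(lhs_c[5, :5], lhs_obs[2, :], atol=1e-8)
        assert lhs_c[5, 5] == pytest.approx(lhs_obs[2, 2])
        # solutions on the complete set map back: duplicate pair collapses
        g_c = rng.normal(size=6)
        g_i = map_solutions(imap, g_c)
        T = np.column_stack([np.eye(5), np.eye(5)[:, 2]])
        np.testing.assert_allclose(g_i, T @ g_c, atol=1e-8)

    def test_imputed_lhs_symmetric_psd(self):
        ref = _random_panel(60, 12, seed=9)
        imap = build_T(ref, ref.snp_ids[::2], ref.snp_ids, block_size=6,
                       ridge=0.0)
        rng = np.random.default_rng(1)
        B = rng.normal(size=(6, 6))
        lhs_obs = B @ B.T
        out = impute_lhs(imap, lhs_obs)
        np.testing.assert_allclose(out, out.T)
        eig = np.linalg.eigvalsh(out)
        assert eig[0] >= -1e-8 * max(eig[-1], 1.0)

    def test_alignment_mismatch_rejected(self):
        ref = _random_panel(30, 6, seed=10)
        imap = build_T(ref, ref.snp_ids[:4], ref.snp_ids, block_size=6)
        with pytest.raises(AlignmentError):
            impute_rhs(imap, np.zeros(5))
        with pytest.raises(AlignmentError):
            impute_lhs(imap, np.zeros((3, 3)))


class TestMaskAndEvaluate:
    def test_reproducible_bit_for_bit(self, single_pop_dataset):
        data, sims = single_pop_dataset
        kw = dict(err_var=10.0, dgv_var=1.0, mask_fraction=0.3,
                  n_replicates=2, seed=21, block_size=100)
        a = mask_and_evaluate(data.panels[0], sims[0].records, **kw)
        b = mask_and_evaluate(data.panels[0], sims[0].records, **kw)
        assert a.replicates.equals(b.replicates)

    def test_accuracy_approaches_one_as_masking_vanishes(self,
                                                         single_pop_dataset):
        data, sims = single_pop_dataset
        ev = mask_and_evaluate(data.panels[0], sims[0].records,
                               err_var=10.0, dgv_var=1.0,
                               mask_fraction=0.02, n_replicates=3,
                               seed=22, block_size=100)
        means = ev.summary["mean"]
        assert means["corr_lhs"] > 0.95
        assert means["corr_rhs"] > 0.95
        # observed entries pass through T unchanged; only masked ones differ
        assert abs(means["acc_imputed"] - means["acc_full"]) < 0.02

    def test_accuracy_ordering_lhs_rhs_above_g(self, single_pop_dataset):
        data, sims = single_pop_dataset
        ev = mask_and_evaluate(data.panels[0], sims[0].records,
                               err_var=10.0, dgv_var=1.0, mask_fraction=0.5,
                               n_replicates=3, seed=23, block_size=100)
        s = ev.summary["mean"]
        assert s["corr_lhs"] >= s["corr_g"]
        assert s["corr_rhs"] >= s["corr_g"]

    def test_invalid_fraction_rejected(self, single_pop_dataset):
        data, sims = single_pop_dataset
        with pytest.raises(DomainError):
            mask_and_evaluate(data.panels[0], sims[0].records,
                              err_var=10.0, dgv_var=1.0, mask_fraction=1.5,
                              n_replicates=1, seed=0)


def test_fully_masked_block_recorded_not_fatal():
    ref = _random_panel(40, 10, seed=13)
    observed = ref.snp_ids[5:]  # first 5-SNP block has no observed SNP
    imap = build_T(ref, observed, ref.snp_ids, block_size=5, ridge=0.0)
    assert imap.empty_blocks == [0]
    rhs = impute_rhs(imap, np.ones(5))
    np.testing.assert_array_equal(rhs[:5], 0.0)
    assert np.abs(rhs[5:]).sum() > 0
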