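"""Filter-cascade, HWE, quantile-normalization and PCA tests."""

import numpy as np
import pytest
from scipy.special import gammaln

from cisqtl.io import SnpAnnotation
from cisqtl.qc import (
    control_probe_pcs,
    filter_cpg_probes,
    filter_expression_probes,
    hwe_exact_p,
    log2_offset_transform,
    quantile_normalize,
    snp_qc,
)

from conftest import make_genotypes, make_probe_matrix


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Brute-force exact HWE p: enumerate every heterozygote count
    compatible with the allele counts and sum probabilities <= observed."""
    n = n_AA + n_Aa + n_aa
    na = 2 * n_aa + n_Aa
    nA = 2 * n_AA + n_aa * 0 + n_Aa  # = 2n - na
    nA = 2 * n - na
    rare = min(na, nA)
    support = list(range(rare % 2, rare + 1, 2))

    def logprob(h):
        naa = (rare - h) // 2
        nAA_ = n - h - naa
        return (h * np.log(2) - gammaln(h + 1) - gammaln(naa + 1)
                - gammaln(nAA_ + 1))

    logs = np.array([logprob(h) for h in support])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[support.index(n_Aa)]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


class TestHweExact:
    def test_two_hets_only(self):
        # 2 A and 2 a alleles: het count in {0, 2}; observed maximal-het table
        assert hwe_exact_p(0, 2, 0) == pytest.approx(
            hwe_enumeration_oracle(0, 2, 0), abs=1e-12)

    def test_5_0_5_matches_enumeration(self):
        assert hwe_exact_p(5, 0, 5) == pytest.approx(
            hwe_enumeration_oracle(5, 0, 5), abs=1e-12)

    def test_monomorphic_is_one(self):
        assert hwe_exact_p(100, 0, 0) == 1.0

    @pytest.mark.parametrize("counts", [(25, 50, 25), (40, 20, 40), (3, 14, 8),
                                        (12, 1, 0), (0, 1, 12)])
    def test_matches_oracle_general(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), abs=1e-12)

    def test_equilibrium_counts_keepable(self):
        assert hwe_exact_p(25, 50, 25) > 0.5


class TestSnpQc:
    def test_call_rate_removal_attribution(self):
        col = [0.0, 1.0, 2.0, 1.0, 1.0, 0.0, 2.0, 1.0, 1.0, np.nan]
        gm = make_genotypes({"rs_missing": col})
        kept, report = snp_qc(gm, call_rate_min=0.97, maf_min=0.01, hwe_p_min=1e-6)
        assert kept.n_snps == 0
        assert report.n_removed_per_rule["call_rate"] == 1

    def test_hwe_equilibrium_kept(self):
        col = [0] * 25 + [1] * 50 + [2] * 25
        gm = make_genotypes({"rs_hwe": col})
        kept, _ = snp_qc(gm, call_rate_min=0.9, maf_min=0.01, hwe_p_min=1e-6)
        assert kept.n_snps == 1

    def test_five_snp_panel_hand_evaluated(self):
        n = 100
        good = [0] * 25 + [1] * 50 + [2] * 25
        low_maf = [0] * 99 + [1]                      # maf 0.005
        bad_call = good[:90] + [np.nan] * 10          # call rate 0.90
        bad_hwe = [0] * 50 + [2] * 50                 # no hets: exact p ~ 0
        good2 = [0] * 36 + [1] * 48 + [2] * 16        # p=0.4, HWE proportions
        gm = make_genotypes({"ok1": good, "maf": low_maf, "call": bad_call,
                             "hwe": bad_hwe, "ok2": good2})
        kept, report = snp_qc(gm, call_rate_min=0.97, maf_min=0.03, hwe_p_min=1e-6)
        assert kept.snp_ids == ["ok1", "ok2"]
        assert report.n_removed_per_rule == {"call_rate": 1, "maf": 1, "hwe": 1}
        report.validate()

    def test_order_independent(self, cohort110):
        _, gm, _ = cohort110
        kept_a, _ = snp_qc(gm, 0.97, 0.05, 1e-6)
        perm = np.random.default_rng(0).permutation(gm.n_snps)
        kept_b, _ = snp_qc(gm.subset_snps(perm), 0.97, 0.05, 1e-6)
        assert set(kept_a.snp_ids) == set(kept_b.snp_ids)


class TestCpgFilter:
    def test_detection_p_rule(self):
        n = 100
        pm = make_probe_matrix(np.full((n, 1), 0.5), positions=[1000])
        det = np.zeros((n, 1))
        det[:6, 0] = 0.02  # 6% of samples above 0.01
        _, report = filter_cpg_probes(pm, detection_p=det)
        assert report.n_removed_per_rule["detection_p"] == 1

    def test_cis_window_boundary_inclusive(self):
        snp = SnpAnnotation("rs1", "chr1", 1_000_000, "A", "G", 0.3)
        pm = make_probe_matrix(np.full((5, 2), 0.5),
                               positions=[1_500_000, 1_500_001])
        kept, report = filter_cpg_probes(pm, snp_annotation=[snp],
                                         cis_window=500_000)
        assert kept.probe_ids == ["cg0"]
        assert report.n_removed_per_rule["no_cis_snp"] == 1

    def test_ten_probe_cascade_first_fail_attribution(self):
        n = 100
        vals = np.full((n, 10), 0.5)
        pm = make_probe_matrix(vals, positions=[1000 + 10 * j for j in range(10)])
        det = np.zeros((n, 10))
        det[:5, 0] = 0.05           # probe 0: rule (i)
        beads = np.full((n, 10), 10.0)
        beads[:5, 1] = 1.0          # probe 1: rule (ii)
        crosshyb = {"cg2"}          # probe 2: rule (iii)
        snp_probes = {"cg3"}        # probe 3: rule (iv)
        snps = [SnpAnnotation("rs1", "chr1", 1000, "A", "G", 0.3)]
        pm.probes[4] = pm.probes[4].__class__(
            probe_id="cg4", chrom="chr2", anchor_pos=1000)  # rule (v): no SNP
        kept, report = filter_cpg_probes(
            pm, detection_p=det, bead_counts=beads, crosshyb_list=crosshyb,
            snp_probe_list=snp_probes, snp_annotation=snps, cis_window=500_000)
        assert kept.n_probes == 5
        assert report.n_removed_per_rule == {
            "detection_p": 1, "bead_count": 1, "crosshyb": 1,
            "snp_probe": 1, "no_cis_snp": 1}
        report.validate()


class TestExpressionFilter:
    def test_weak_probe_removed(self):
        n = 100
        pm = make_probe_matrix(np.full((n, 1), 7.0), positions=[1000],
                               value_kind="log2_expression", prefix="tx")
        det = np.full((n, 1), 0.5)
        det[:4, 0] = 0.01  # detected in only 4% of samples: weak in 96% >= 95%
        _, report = filter_expression_probes(pm, detection_p=det)
        assert report.n_removed_per_rule["weak_expression"] == 1

    def test_six_probe_fixture(self):
        n = 100
        pm = make_probe_matrix(np.full((n, 6), 7.0),
                               positions=[1000 * (j + 1) for j in range(6)],
                               value_kind="log2_expression", prefix="tx")
        det = np.zeros((n, 6))
        det[:, 0] = 0.5
        det[:, 1] = 0.5          # two weak probes
        kept, report = filter_expression_probes(
            pm, detection_p=det, crosshyb_list={"tx2"})
        assert kept.n_probes == 3
        assert report.n_removed_per_rule == {"weak_expression": 2, "crosshyb": 1,
                                             "snp_probe": 0}


class TestQuantileNormalize:
    def test_identical_samples_unchanged(self):
        row = np.array([3.0, 1.0, 2.0, 5.0])
        mat = np.vstack([row, row])
        np.testing.assert_allclose(quantile_normalize(mat), mat, atol=1e-12)

    def test_hand_computed_3x4(self):
        mat = np.array([[5.0, 2.0, 3.0, 4.0],
                        [4.0, 1.0, 4.0, 2.0],
                        [3.0, 4.0, 6.0, 8.0]])
        # rank/mean construction: mean order statistics across samples
        sorted_rows = np.sort(mat, axis=1)
        ref = sorted_rows.mean(axis=0)  # [2, 3.3333, 4.3333, 5.6667]
        out = quantile_normalize(mat)
        # sample 0 ranks: 4,1,2,3 -> ref[3],ref[0],ref[1],ref[2]
        np.testing.assert_allclose(out[0], [ref[3], ref[0], ref[1], ref[2]],
                                   atol=1e-10)
        # sample 1 has a tie at rank 3.5 between the two 4.0s
        tied = (ref[2] + ref[3]) / 2
        np.testing.assert_allclose(out[1], [tied, ref[0], tied, ref[1]], atol=1e-10)
        np.testing.assert_allclose(out[2], [ref[0], ref[1], ref[2], ref[3]],
                                   atol=1e-10)

    def test_common_distribution_postcondition(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(6, 50))
        out = quantile_normalize(mat)
        base = np.sort(out[0])
        for i in range(1, 6):
            np.testing.assert_allclose(np.sort(out[i]), base, atol=1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(size=(5, 40))
        once = quantile_normalize(mat)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice, once, atol=1e-10)

    def test_subsets_normalized_independently(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(4, 20))
        subsets = [np.arange(10), np.arange(10, 20)]
        out = quantile_normalize(mat, subsets)
        for sub in subsets:
            base = np.sort(out[0, sub])
            for i in range(1, 4):
                np.testing.assert_allclose(np.sort(out[i, sub]), base, atol=1e-10)

    def test_missing_restored(self):
        mat = np.array([[1.0, np.nan, 3.0, 2.0],
                        [4.0, 2.0, 1.0, 3.0],
                        [2.0, 3.0, 4.0, 1.0]])
        out = quantile_normalize(mat)
        assert np.isnan(out[0, 1])
        assert np.isfinite(out[[0, 0, 0], [0, 2, 3]]).all()


class TestLog2Offset:
    @pytest.mark.parametrize("v,expected", [(0.0, 4.0), (16.0, 5.0), (48.0, 6.0)])
    def test_reference_points(self, v, expected):
        pm = make_probe_matrix(np.array([[v]]), positions=[100],
                               value_kind="log2_expression", prefix="tx")
        out = log2_offset_transform(pm)
        assert out.values[0, 0] == pytest.approx(expected)

    def test_below_offset_error(self):
        pm = make_probe_matrix(np.array([[-16.0]]), positions=[100],
                               value_kind="log2_expression", prefix="tx")
        with pytest.raises(ValueError):
            log2_offset_transform(pm)


class TestControlProbePcs:
    def test_rank1_matrix(self):
        u = np.arange(1.0, 9.0)
        v = np.array([2.0, -1.0, 3.0])
        scores, props = control_probe_pcs(np.outer(u, v), n_pcs=2)
        assert props[0] == pytest.approx(1.0, abs=1e-12)

    def test_svd_oracle_agreement(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 15))
        scores, props = control_probe_pcs(X, n_pcs=4)
        Xc = X - X.mean(axis=0)
        u, s, _ = np.linalg.svd(Xc, full_matrices=False)
        expected = u[:, :4] * s[:4]
        for k in range(4):
            dot = np.dot(scores[:, k], expected[:, k])
            np.testing.assert_allclose(scores[:, k], np.sign(dot) * expected[:, k],
                                       atol=1e-8)
        assert np.all(np.diff(props) <= 1e-12)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            control_probe_pcs(np.random.default_rng(0).normal(size=(3, 10)), n_pcs=6)
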