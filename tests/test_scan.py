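"""QTL engine: pair enumeration, OLS against a closed-form oracle, BH-FDR,
variance decomposition, and scan composition/invariance properties."""

import numpy as np
import pytest
from scipy import stats

from cisqtl.io import CovariateTable, ProbeAnnotation, SnpAnnotation
from cisqtl.scan import (
    AlignmentError,
    ScanConfig,
    bh_fdr,
    compute_genotype_pcs,
    enumerate_cis_pairs,
    fit_additive_model,
    hidden_confounder_pcs,
    residualize,
    run_cis_scan,
    variance_decomposition,
)

from conftest import make_genotypes, make_probe_matrix


def ols_oracle(y, X):
    """Normal-equations + t-distribution oracle for the coefficient of X[:,1]."""
    XtX = X.T @ X
    coef = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ coef
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[1, 1])
    t = coef[1] / se
    p = 2 * stats.t.sf(abs(t), df)
    return coef[1], se, t, p


class TestEnumerateCisPairs:
    def snp(self, pos, chrom="chr1", sid=None):
        return SnpAnnotation(sid or f"rs{pos}", chrom, pos, "A", "G", 0.3)

    def probe(self, pos, chrom="chr1", pid=None):
        return ProbeAnnotation(pid or f"cg{pos}", chrom, pos)

    def test_window_boundary_inclusive(self):
        snps = [self.snp(1_000_000)]
        inside = enumerate_cis_pairs(snps, [self.probe(1_500_000)], 500_000)
        outside = enumerate_cis_pairs(snps, [self.probe(1_500_001)], 500_000)
        assert inside == [(0, 0)] and outside == []

    def test_cross_chromosome_excluded(self):
        pairs = enumerate_cis_pairs([self.snp(100)],
                                    [self.probe(100, chrom="chr2")], 500_000)
        assert pairs == []

    def test_matches_brute_force_grid(self):
        snps = [self.snp(100_000 * (k + 1), sid=f"rs{k}") for k in range(10)]
        probes = [self.probe(550_000)]
        fast = set(enumerate_cis_pairs(snps, probes, 500_000))
        brute = {(i, j) for i, s in enumerate(snps) for j, p in enumerate(probes)
                 if s.chrom == p.chrom and abs(s.pos - p.anchor_pos) <= 500_000}
        assert fast == brute and len(fast) == 10


class TestGenotypePcs:
    def test_separates_subpopulations(self):
        rng = np.random.default_rng(1)
        n, m = 60, 80
        p1 = rng.uniform(0.1, 0.4, m)
        p2 = np.clip(p1 + rng.choice([-0.25, 0.25], m), 0.05, 0.95)
        d1 = rng.binomial(2, p1, size=(n // 2, m)).astype(float)
        d2 = rng.binomial(2, p2, size=(n // 2, m)).astype(float)
        gm = make_genotypes(
            {f"rs{j}": np.concatenate([d1[:, j], d2[:, j]]) for j in range(m)})
        pcs = compute_genotype_pcs(gm, 3)
        between = abs(pcs[: n // 2, 0].mean() - pcs[n // 2:, 0].mean())
        within = max(pcs[: n // 2, 0].std(), pcs[n // 2:, 0].std())
        assert between > within

    def test_scores_orthogonal(self, cohort110):
        _, gm, _ = cohort110
        pcs = compute_genotype_pcs(gm, 3)
        g = pcs.T @ pcs
        off = g - np.diag(np.diag(g))
        assert np.abs(off).max() < 1e-8


class TestResidualize:
    def test_covariate_residual_is_zero(self):
        rng = np.random.default_rng(2)
        c = rng.normal(size=20)
        resid = residualize(c[:, None].copy(), c[:, None])
        assert np.linalg.norm(resid) < 1e-10

    def test_orthogonal_y_untouched(self):
        rng = np.random.default_rng(3)
        c = rng.normal(size=50)
        y = rng.normal(size=50)
        X = np.column_stack([np.ones(50), c])
        y_orth = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        resid = residualize(y_orth[:, None], c[:, None])
        np.testing.assert_allclose(resid[:, 0], y_orth, atol=1e-10)

    def test_projection_matrix_oracle(self):
        rng = np.random.default_rng(4)
        C = rng.normal(size=(12, 2))
        Y = rng.normal(size=(12, 3))
        X = np.column_stack([np.ones(12), C])
        P = X @ np.linalg.inv(X.T @ X) @ X.T
        expected = Y - P @ Y
        np.testing.assert_allclose(residualize(Y, C), expected, atol=1e-10)

    def test_collinear_design_rejected(self):
        c = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            residualize(np.random.default_rng(0).normal(size=(10, 2)),
                        np.column_stack([c, 2 * c]))


class TestHiddenPcs:
    def test_planted_latent_factor_found(self):
        rng = np.random.default_rng(5)
        n, m = 60, 500
        factor = rng.normal(size=n)
        load = rng.normal(size=m)
        resid = np.outer(factor, load) + 0.5 * rng.normal(size=(n, m))
        scores, props = hidden_confounder_pcs(resid, 3)
        assert props[0] > props[1]
        r = np.corrcoef(scores[:, 0], factor)[0, 1]
        assert abs(r) > 0.9

    def test_svd_agreement_and_monotone_props(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 40))
        scores, props = hidden_confounder_pcs(X, 5)
        Xc = X - X.mean(axis=0)
        u, s, _ = np.linalg.svd(Xc, full_matrices=False)
        for k in range(5):
            dot = scores[:, k] @ (u[:, k] * s[k])
            np.testing.assert_allclose(scores[:, k], np.sign(dot) * u[:, k] * s[k],
                                       atol=1e-8)
        assert np.all(np.diff(props) <= 1e-12) and props.max() <= 1.0

    def test_rank_exceeded(self):
        with pytest.raises(ValueError, match="rank"):
            hidden_confounder_pcs(np.ones((5, 3)) * np.arange(3), 2)


class TestFitAdditiveModel:
    def test_exact_linear_relation(self):
        g = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 1], dtype=float)
        y = 0.05 * g
        beta, se, t, p = fit_additive_model(y, g)
        assert beta == pytest.approx(0.05, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-10)

    def test_monomorphic_raises(self):
        with pytest.raises(ValueError, match="monomorphic"):
            fit_additive_model(np.random.default_rng(0).normal(size=10),
                               np.ones(10))

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(12, 51))
            g = rng.binomial(2, 0.3, n).astype(float)
            if g.std() == 0:
                continue
            c = rng.normal(size=n)
            y = 0.3 * g + 0.5 * c + rng.normal(size=n)
            beta, se, t, p = fit_additive_model(y, g, c[:, None])
            X = np.column_stack([np.ones(n), g, c])
            eb, es, et, ep = ols_oracle(y, X)
            assert beta == pytest.approx(eb, abs=1e-8)
            assert se == pytest.approx(es, abs=1e-8)
            assert t == pytest.approx(et, abs=1e-6)
            assert p == pytest.approx(ep, rel=1e-6)


class TestBhFdr:
    def test_all_ones_none_significant(self):
        flags, thr = bh_fdr(np.ones(10), 0.01)
        assert not flags.any() and thr == 0.0

    def test_matches_brute_force_stepup(self):
        p = np.array([0.001, 0.002, 0.009, 0.5])
        flags, thr = bh_fdr(p, 0.01)
        # brute force: largest k with p_(k) <= k/m * alpha
        m = len(p)
        ranked = np.sort(p)
        ks = [k for k in range(1, m + 1) if ranked[k - 1] <= 0.01 * k / m]
        kmax = max(ks)
        expected = p <= ranked[kmax - 1]
        np.testing.assert_array_equal(flags, expected)
        assert thr == ranked[kmax - 1]

    def test_single_small_p(self):
        flags, _ = bh_fdr(np.array([0.005]), 0.01)
        assert flags[0]

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = np.concatenate([rng.uniform(0, 1e-4, 20), rng.uniform(0, 1, 500)])
        flags, _ = bh_fdr(p, 0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        np.testing.assert_array_equal(flags, ref)


class TestVarianceDecomposition:
    def test_orthogonal_shares_sum_to_r2(self):
        rng = np.random.default_rng(9)
        n = 64
        g = np.tile([0, 1], n // 2).astype(float)
        c = np.tile([0, 0, 1, 1], n // 4).astype(float)
        g_, c_ = g - g.mean(), c - c.mean()
        assert abs(g_ @ c_) < 1e-10
        y = 0.7 * g + 0.4 * c + rng.normal(size=n)
        shares = variance_decomposition(y, g, {"c": c})
        X = np.column_stack([np.ones(n), g, c])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        r2_full = 1 - resid @ resid / ((y - y.mean()) ** 2).sum()
        assert shares["genotype"] + shares["c"] == pytest.approx(r2_full, abs=1e-10)

    def test_null_term_share_near_zero(self):
        rng = np.random.default_rng(10)
        n = 2000
        g = rng.binomial(2, 0.3, n).astype(float)
        c = rng.normal(size=n)  # independent of y
        y = 0.2 * g + rng.normal(size=n)
        shares = variance_decomposition(y, g, {"c": c})
        assert shares["c"] < 0.01

    def test_planted_genotype_share_recovered(self):
        rng = np.random.default_rng(11)
        n = 2000
        g = rng.binomial(2, 0.3, n).astype(float)
        gs = (g - g.mean()) / g.std()
        y = np.sqrt(0.24) * gs + np.sqrt(0.76) * rng.normal(size=n)
        shares = variance_decomposition(y, g, {})
        assert 0.20 <= shares["genotype"] <= 0.28

    def test_no_covariate_equals_t2_identity(self):
        rng = np.random.default_rng(12)
        n = 40
        g = rng.binomial(2, 0.4, n).astype(float)
        y = 0.3 * g + rng.normal(size=n)
        beta, se, t, p = fit_additive_model(y, g)
        df = n - 2
        shares = variance_decomposition(y, g, {})
        assert shares["genotype"] == pytest.approx(t**2 / (t**2 + df), abs=1e-10)


class TestRunCisScan:
    def _toy(self, seed=13, n=110):
        from cisqtl.synth import (PlantedEffect, SimulationConfig,
                                  make_covariates, simulate_genotypes,
                                  simulate_methylation)

        cfg = SimulationConfig(
            n_samples=n, n_snps=100, ld_block_size=10, seed=seed,
            n_meth_probes=40,
            planted_meqtls=[PlantedEffect(15, 0, 0.5), PlantedEffect(55, 1, 0.35)])
        gm = simulate_genotypes(cfg)
        cov = make_covariates(n, seed)
        meth = simulate_methylation(gm, cfg, cov)
        return gm, meth, cov

    def test_misalignment_rejected(self):
        gm, meth, cov = self._toy()
        meth.samples = list(reversed(meth.samples))
        with pytest.raises(AlignmentError):
            run_cis_scan(gm, meth, cov, ScanConfig())

    def test_single_pair_equals_fit_additive_model(self):
        gm, meth, cov = self._toy()
        gm1 = gm.subset_snps([15])
        meth1 = meth.subset_probes([0])
        cfg = ScanConfig(n_genotype_pcs=0, n_hidden_pcs=0)
        recs, _ = run_cis_scan(gm1, meth1, cov, cfg, keep="all")
        assert len(recs) == 1
        C = cov.matrix(["neuronal_proportion", "age_years", "gender"])
        beta, se, t, p = fit_additive_model(meth1.values[:, 0],
                                            gm1.dosage[:, 0], C)
        r = recs[0]
        assert r.beta == pytest.approx(beta, abs=1e-10)
        assert r.se == pytest.approx(se, abs=1e-10)
        assert r.t_stat == pytest.approx(t, rel=1e-8)
        assert r.p_value == pytest.approx(p, rel=1e-6)

    def test_planted_effects_detected(self):
        gm, meth, cov = self._toy()
        recs, summary = run_cis_scan(gm, meth, cov, ScanConfig())
        sig_probes = {r.probe_id for r in recs if r.fdr_significant}
        assert "cg00000" in sig_probes
        assert summary.n_significant_pairs >= summary.n_significant_probes

    def test_input_order_invariance(self):
        gm, meth, cov = self._toy()
        recs_a, _ = run_cis_scan(gm, meth, cov, ScanConfig())
        perm = np.random.default_rng(14).permutation(gm.n_snps)
        recs_b, _ = run_cis_scan(gm.subset_snps(perm), meth, cov, ScanConfig())
        key = lambda r: (r.snp_id, r.probe_id)
        a = {key(r): r.p_value for r in recs_a}
        b = {key(r): r.p_value for r in recs_b}
        assert set(a) == set(b)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-9)

    def test_meqtl_beta_bounded_by_beta_scale(self):
        gm, meth, cov = self._toy()
        recs, _ = run_cis_scan(gm, meth, cov, ScanConfig())
        for r in recs:
            assert abs(r.beta) <= 1.0

    def test_parameter_recovery_large_n(self):
        # planted beta-scale effect recovered with small bias at n=2000
        from cisqtl.synth import (PlantedEffect, SimulationConfig,
                                  simulate_genotypes, simulate_methylation)

        cfg = SimulationConfig(
            n_samples=2000, n_snps=20, ld_block_size=10, seed=15,
            n_meth_probes=4, covariate_variance={},
            planted_meqtls=[PlantedEffect(5, 0, 0.5)])
        gm = simulate_genotypes(cfg)
        meth = simulate_methylation(gm, cfg)
        recs, _ = run_cis_scan(
            gm.subset_snps([5]), meth.subset_probes([0]), None,
            ScanConfig(n_genotype_pcs=0, n_hidden_pcs=0), keep="all")
        r = recs[0]
        # oracle: direct OLS slope
        X = np.column_stack([np.ones(2000), gm.dosage[:, 5]])
        coef, *_ = np.linalg.lstsq(X, meth.values[:, 0], rcond=None)
        assert r.beta == pytest.approx(coef[1], abs=1e-10)
        assert r.r2_genotype == pytest.approx(0.5, abs=0.06)
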