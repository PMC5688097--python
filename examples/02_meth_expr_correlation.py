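"""Detect methylation-expression correlations driven by a shared SNP.

Plants the same SNP as both a meQTL and an eQTL; the CpG and transcript
then correlate through their shared genetic driver, which
find_shared_drivers identifies from the top SNP of each scan.
"""

from cisqtl.methexpr import correlate_cis, find_shared_drivers
from cisqtl.scan import ScanConfig, residualize, run_cis_scan
from cisqtl.synth import (
    PlantedEffect,
    SimulationConfig,
    make_covariates,
    simulate_expression,
    simulate_genotypes,
    simulate_methylation,
)

cfg = SimulationConfig(
    n_samples=110, n_snps=100, ld_block_size=10, seed=2,
    n_meth_probes=30, n_expr_probes=20,
    planted_meqtls=[PlantedEffect(45, 0, 0.5)],
    planted_eqtls=[PlantedEffect(45, 0, 0.5)],  # same SNP drives both
)
gm = simulate_genotypes(cfg)
cov = make_covariates(cfg.n_samples, cfg.seed)
meth = simulate_methylation(gm, cfg, cov)
expr = simulate_expression(gm, cfg, cov)

scan = ScanConfig(fdr_level=0.01)
meqtl, _ = run_cis_scan(gm, meth, cov, scan)
eqtl, _ = run_cis_scan(gm, expr, cov, ScanConfig(fdr_level=0.01, n_hidden_pcs=2))

C = cov.matrix(["neuronal_proportion", "age_years", "gender"])
corr = correlate_cis(residualize(meth, C), residualize(expr, C))
sig = [r for r in corr if r.fdr_significant]
print(f"significant CpG-transcript correlations: {len(sig)}")
for r in sig[:3]:
    print(f"  {r.cpg_id} ~ {r.expr_probe_id}: r={r.pearson_r:+.2f} "
          f"R2={r.r_squared:.2f} p={r.p_value:.2e}")

drivers = find_shared_drivers(meqtl, eqtl, corr, gm, r2_min=0.4)
for d in drivers:
    print(f"shared driver: {d.meqtl_snp} / {d.eqtl_snp} "
          f"(r2={d.r2_between_snps:.2f}) links {d.cpg_id} and {d.expr_probe_id}")
# r2 = 1.00 because the planted meQTL and eQTL top SNPs coincide.
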