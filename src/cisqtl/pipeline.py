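"""End-to-end orchestration: configuration, per-stage seeding, stage
execution in dependency order, and a deterministic run manifest.

Stages communicate through TSV files in the output directory, so any
downstream stage can be rerun from cached inputs. Per-stage seeds are
derived from the master seed with ``SeedSequence(master, spawn_key=
(stage_counter,))`` using a fixed counter per stage name, so inserting a
stage never perturbs another stage's randomness. Output files carry a
'#'-prefixed provenance header (version, seed, parameters) and contain
no timestamps; the manifest hash is therefore a pure function of
(inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annot import run_annotation_enrichment
from .io import (
    CovariateTable,
    read_covariates,
    read_genotypes,
    read_probe_matrix,
    read_qtl_table,
    write_covariates,
    write_genotypes_tsv,
    write_genotypes_vcf,
    write_probe_matrix,
    write_qtl_table,
)
from .ldenrich import OverlapConfig, run_overlap_enrichment
from .methexpr import correlate_cis, find_shared_drivers
from .qc import snp_qc
from .scan import ScanConfig, bh_fdr, residualize, run_cis_scan
from .synth import (
    PlantedEffect,
    SimulationConfig,
    make_covariates,
    simulate_expression,
    simulate_genotypes,
    simulate_gwas_list,
    simulate_methylation,
    simulate_tracks,
)

__all__ = ["RunConfig", "validate_config", "run_pipeline", "STAGES"]

# fixed seed counters: stage insertion never shifts another stage's stream
STAGE_SEED_COUNTER = {
    "simulate": 0,
    "qc": 1,
    "scan-meqtl": 2,
    "scan-eqtl": 3,
    "correlate": 4,
    "enrich-annotation": 5,
    "enrich-ld": 6,
}
STAGES = list(STAGE_SEED_COUNTER)


@dataclass
class RunConfig:
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    # simulation
    n_samples: int = 110
    n_snps: int = 300
    ld_block_size: int = 10
    within_block_r2_target: float = 0.8
    n_meth_probes: int = 120
    n_expr_probes: int = 60
    n_planted_meqtls: int = 8
    n_planted_eqtls: int = 5
    planted_variance: float = 0.4
    # scan
    window_kb: float = 500.0
    fdr: float = 0.01
    n_genotype_pcs: int = 3
    n_hidden_pcs_meth: int = 3
    n_hidden_pcs_expr: int = 2
    # qc
    call_rate_min: float = 0.97
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    # enrichment
    match_ratio: int = 7
    clump_r2: float = 0.25
    clump_window_kb: float = 250.0
    overlap_window_kb: float = 250.0
    # coarse bins: desk-scale clumped pools are far smaller than a
    # genome-wide SNP panel, so 0.02-wide bins would often be empty
    maf_bin_width: float = 0.1
    n_null_sets: int = 1000
    track_odds: float = 1.8
    gwas_n_hits: int = 12
    gwas_overlap_fraction: float = 0.5

    @property
    def window_bp(self) -> int:
        return int(self.window_kb * 1000)


def validate_config(raw: dict | None) -> RunConfig:
    """Type/range-check a raw (YAML) mapping, filling defaults; an empty
    config yields the fully defaulted RunConfig."""
    raw = dict(raw or {})
    errors: list[str] = []
    known = {f for f in RunConfig.__dataclass_fields__}
    for key in raw:
        if key not in known:
            errors.append(f"unknown parameter {key!r}")
    cfg_kwargs = {k: v for k, v in raw.items() if k in known}
    cfg = RunConfig(**cfg_kwargs)
    if not 0.0 < cfg.fdr < 1.0:
        errors.append(f"fdr must lie in (0, 1), got {cfg.fdr}")
    if cfg.window_kb <= 0:
        errors.append(f"window_kb must be > 0, got {cfg.window_kb}")
    if not 0.0 < cfg.clump_r2 < 1.0:
        errors.append(f"clump_r2 must lie in (0, 1), got {cfg.clump_r2}")
    if cfg.match_ratio < 1:
        errors.append("match_ratio must be >= 1")
    if cfg.n_samples < 10:
        errors.append("n_samples must be >= 10")
    for stage in cfg.stages:
        if stage not in STAGES:
            errors.append(f"unknown stage {stage!r}")
    if errors:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return cfg


def _stage_seed(cfg: RunConfig, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(cfg.seed, spawn_key=(STAGE_SEED_COUNTER[stage],))


def _seed_int(cfg: RunConfig, stage: str) -> int:
    return int(_stage_seed(cfg, stage).generate_state(1)[0] % (2**31))


def _provenance(cfg: RunConfig, stage: str) -> list[str]:
    return [f"cisqtl {__version__}", f"stage={stage}", f"seed={cfg.seed}"]


def _sim_config(cfg: RunConfig) -> SimulationConfig:
    rng = np.random.default_rng(_seed_int(cfg, "simulate"))
    snap = max(1, cfg.n_snps // max(cfg.n_planted_meqtls, 1))
    planted_me = [
        PlantedEffect(snp_index=int(i * snap) % cfg.n_snps,
                      probe_index=i, variance_explained=cfg.planted_variance)
        for i in range(cfg.n_planted_meqtls)
    ]
    enap = max(1, cfg.n_snps // max(cfg.n_planted_eqtls, 1))
    planted_e = [
        PlantedEffect(snp_index=int((i * enap + enap // 2)) % cfg.n_snps,
                      probe_index=i, variance_explained=cfg.planted_variance)
        for i in range(cfg.n_planted_eqtls)
    ]
    del rng
    return SimulationConfig(
        n_samples=cfg.n_samples,
        n_snps=cfg.n_snps,
        ld_block_size=cfg.ld_block_size,
        within_block_r2_target=cfg.within_block_r2_target,
        n_meth_probes=cfg.n_meth_probes,
        n_expr_probes=cfg.n_expr_probes,
        planted_meqtls=planted_me,
        planted_eqtls=planted_e,
        seed=_seed_int(cfg, "simulate"),
    )


def _stage_simulate(outdir: str, cfg: RunConfig):
    sim = _sim_config(cfg)
    cov = make_covariates(cfg.n_samples, sim.seed)
    gm = simulate_genotypes(sim)
    meth = simulate_methylation(gm, sim, cov)
    expr = simulate_expression(gm, sim, cov)
    prov = _provenance(cfg, "simulate")
    write_genotypes_tsv(gm, os.path.join(outdir, "genotypes.tsv"), prov)
    write_genotypes_vcf(gm, os.path.join(outdir, "genotypes.vcf"))
    write_probe_matrix(meth, os.path.join(outdir, "methylation.tsv"),
                       os.path.join(outdir, "methylation_annotation.tsv"), prov)
    write_probe_matrix(expr, os.path.join(outdir, "expression.tsv"),
                       os.path.join(outdir, "expression_annotation.tsv"), prov)
    write_covariates(cov, os.path.join(outdir, "covariates.tsv"), prov)
    for name, planted in (("truth_meqtls.tsv", sim.planted_meqtls),
                          ("truth_eqtls.tsv", sim.planted_eqtls)):
        with open(os.path.join(outdir, name), "w") as fh:
            fh.write("snp_id\tprobe_id\tvariance_explained\n")
            probes = meth.probes if "me" in name else expr.probes
            for e in planted:
                fh.write(f"{gm.snps[e.snp_index].snp_id}\t"
                         f"{probes[e.probe_index].probe_id}\t"
                         f"{e.variance_explained}\n")


def _stage_qc(outdir: str, cfg: RunConfig):
    gm = read_genotypes(os.path.join(outdir, "genotypes.tsv"), "dosage_tsv")
    kept, report = snp_qc(gm, cfg.call_rate_min, cfg.maf_min, cfg.hwe_p_min)
    write_genotypes_tsv(kept, os.path.join(outdir, "genotypes_qc.tsv"),
                        _provenance(cfg, "qc"))
    with open(os.path.join(outdir, "snp_qc_report.tsv"), "w") as fh:
        fh.write("rule\tn_removed\n")
        for rule, n in report.n_removed_per_rule.items():
            fh.write(f"{rule}\t{n}\n")
        fh.write(f"kept\t{report.n_output}\n")


def _scan_stage(outdir: str, cfg: RunConfig, kind: str):
    gm = read_genotypes(os.path.join(outdir, "genotypes_qc.tsv"), "dosage_tsv")
    cov = read_covariates(os.path.join(outdir, "covariates.tsv"))
    if kind == "meqtl":
        pm = read_probe_matrix(os.path.join(outdir, "methylation.tsv"),
                               os.path.join(outdir, "methylation_annotation.tsv"),
                               "beta")
        scan_cfg = ScanConfig(window_bp=cfg.window_bp, fdr_level=cfg.fdr,
                              n_genotype_pcs=cfg.n_genotype_pcs,
                              n_hidden_pcs=cfg.n_hidden_pcs_meth)
    else:
        pm = read_probe_matrix(os.path.join(outdir, "expression.tsv"),
                               os.path.join(outdir, "expression_annotation.tsv"),
                               "log2_expression")
        scan_cfg = ScanConfig(window_bp=cfg.window_bp, fdr_level=cfg.fdr,
                              n_genotype_pcs=cfg.n_genotype_pcs,
                              n_hidden_pcs=cfg.n_hidden_pcs_expr)
    records, summary = run_cis_scan(gm, pm, cov, scan_cfg, keep="all")
    sig = [r for r in records if r.fdr_significant]
    write_qtl_table(sig, os.path.join(outdir, f"{kind}.tsv"),
                    _provenance(cfg, f"scan-{kind}"))
    # per-SNP statistics at 1% and 10% FDR (10% defines the control pool)
    pvals = np.array([r.p_value for r in records])
    flags10, _ = bh_fdr(pvals, 0.10)
    per_snp: dict[str, dict] = {}
    for r, f10 in zip(records, flags10):
        d = per_snp.setdefault(r.snp_id, {"min_p": 1.0, "sig1": False, "sig10": False})
        d["min_p"] = min(d["min_p"], r.p_value)
        d["sig1"] = d["sig1"] or r.fdr_significant
        d["sig10"] = d["sig10"] or bool(f10)
    with open(os.path.join(outdir, f"{kind}_snp_stats.tsv"), "w") as fh:
        fh.write("snp_id\tmin_p\tsig_fdr1\tsig_fdr10\n")
        for sid in sorted(per_snp):
            d = per_snp[sid]
            fh.write(f"{sid}\t{d['min_p']:.6g}\t{int(d['sig1'])}\t{int(d['sig10'])}\n")
    with open(os.path.join(outdir, f"{kind}_summary.yaml"), "w") as fh:
        yaml.safe_dump(
            {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
             for k, v in asdict(summary).items()},
            fh, sort_keys=True)


def _residual_matrices(outdir: str, cfg: RunConfig):
    cov = read_covariates(os.path.join(outdir, "covariates.tsv"))
    meth = read_probe_matrix(os.path.join(outdir, "methylation.tsv"),
                             os.path.join(outdir, "methylation_annotation.tsv"),
                             "beta")
    expr = read_probe_matrix(os.path.join(outdir, "expression.tsv"),
                             os.path.join(outdir, "expression_annotation.tsv"),
                             "log2_expression")
    C = cov.matrix(["neuronal_proportion", "age_years", "gender"])
    return (residualize(meth, C), residualize(expr, C), cov)


def _stage_correlate(outdir: str, cfg: RunConfig):
    meth_res, expr_res, _ = _residual_matrices(outdir, cfg)
    gm = read_genotypes(os.path.join(outdir, "genotypes_qc.tsv"), "dosage_tsv")
    records = correlate_cis(meth_res, expr_res, window_bp=cfg.window_bp,
                            fdr=cfg.fdr)
    meqtl = read_qtl_table(os.path.join(outdir, "meqtl.tsv"))
    eqtl = read_qtl_table(os.path.join(outdir, "eqtl.tsv"))
    drivers = find_shared_drivers(meqtl, eqtl, records, gm)
    with open(os.path.join(outdir, "correlations.tsv"), "w") as fh:
        for line in _provenance(cfg, "correlate"):
            fh.write(f"# {line}\n")
        fh.write("cpg_id\texpr_probe_id\tdistance_bp\tr\tr_squared\tp\tfdr_significant\n")
        for r in sorted(records, key=lambda x: x.p_value):
            fh.write(f"{r.cpg_id}\t{r.expr_probe_id}\t{r.distance_bp}\t"
                     f"{r.pearson_r:.6g}\t{r.r_squared:.6g}\t{r.p_value:.6g}\t"
                     f"{int(r.fdr_significant)}\n")
    with open(os.path.join(outdir, "shared_drivers.tsv"), "w") as fh:
        fh.write("cpg_id\texpr_probe_id\tmeqtl_snp\teqtl_snp\tr2_between_snps\n")
        for d in drivers:
            fh.write(f"{d.cpg_id}\t{d.expr_probe_id}\t{d.meqtl_snp}\t"
                     f"{d.eqtl_snp}\t{d.r2_between_snps:.6g}\n")


def _stage_enrich_annotation(outdir: str, cfg: RunConfig):
    meth = read_probe_matrix(os.path.join(outdir, "methylation.tsv"),
                             os.path.join(outdir, "methylation_annotation.tsv"),
                             "beta")
    meqtl = read_qtl_table(os.path.join(outdir, "meqtl.tsv"))
    sig_probes = {r.probe_id for r in meqtl if r.fdr_significant}
    med = np.median(meth.values, axis=0)
    targets = {}
    pool = {}
    for j, probe in enumerate(meth.probes):
        entry = (probe.chrom, probe.anchor_pos, float(med[j]))
        (targets if probe.probe_id in sig_probes else pool)[probe.probe_id] = entry
    seed = _seed_int(cfg, "enrich-annotation")
    qtl_flags = np.array([p.probe_id in sig_probes for p in meth.probes])
    track = simulate_tracks(meth.probes, qtl_flags, cfg.track_odds, seed)
    # desk-scale pools may not support the full match ratio in every beta
    # bin: shrink the ratio to what the pool supports and drop targets in
    # bins with no controls at all (recorded in the output header)
    from .annot import assign_beta_bins

    t_bins = assign_beta_bins(np.array([v[2] for v in targets.values()]))
    p_bins = assign_beta_bins(np.array([v[2] for v in pool.values()]))
    t_counts = np.bincount(t_bins, minlength=11)
    p_counts = np.bincount(p_bins, minlength=11)
    occupied = t_counts > 0
    supportable = occupied & (p_counts >= t_counts)
    ratio = int(min(
        cfg.match_ratio,
        (p_counts[supportable] // t_counts[supportable]).min()
        if supportable.any() else 1,
    ))
    ratio = max(ratio, 1)
    dropped_bins = set(np.where(occupied & (p_counts < ratio * t_counts))[0])
    if dropped_bins:
        targets = {k: v for k, v in targets.items()
                   if assign_beta_bins(np.array([v[2]]))[0] not in dropped_bins}
    try:
        records = run_annotation_enrichment(targets, pool, [track],
                                            match_ratio=ratio, seed=seed)
    except ValueError:
        # degenerate 2x2 margins at desk scale (e.g. no covered CpG at all)
        records = []
    extra = [f"match_ratio={ratio}"]
    if dropped_bins:
        extra.append(f"dropped_target_bins={sorted(int(b) for b in dropped_bins)}")
    with open(os.path.join(outdir, "annotation_enrichment.tsv"), "w") as fh:
        for line in _provenance(cfg, "enrich-annotation") + extra:
            fh.write(f"# {line}\n")
        fh.write("track\tratio_target\tratio_control\todds_ratio\tci95_low\t"
                 "ci95_high\tp_value\tq_value\n")
        for r in records:
            fh.write(f"{r.track_name}\t{r.ratio_target:.6g}\t{r.ratio_control:.6g}\t"
                     f"{r.odds_ratio:.6g}\t{r.ci95_low:.6g}\t{r.ci95_high:.6g}\t"
                     f"{r.p_value:.6g}\t{r.q_value:.6g}\n")


def _stage_enrich_ld(outdir: str, cfg: RunConfig):
    gm = read_genotypes(os.path.join(outdir, "genotypes_qc.tsv"), "dosage_tsv")
    stats = pd.read_csv(os.path.join(outdir, "meqtl_snp_stats.tsv"), sep="\t")
    target_p = {r.snp_id: r.min_p for r in stats.itertuples() if r.sig_fdr1 == 1}
    control_p = {r.snp_id: r.min_p for r in stats.itertuples() if r.sig_fdr10 == 0}
    seed = _seed_int(cfg, "enrich-ld")
    gwas = simulate_gwas_list(gm, set(target_p), cfg.gwas_n_hits,
                              cfg.gwas_overlap_fraction, seed,
                              block_size=cfg.ld_block_size)
    ref_p = dict(zip(gwas.records["snp_id"], gwas.records["p_value"]))
    oc = OverlapConfig(
        clump_r2=cfg.clump_r2,
        clump_window_bp=int(cfg.clump_window_kb * 1000),
        overlap_r2=cfg.clump_r2,
        overlap_window_bp=int(cfg.overlap_window_kb * 1000),
        maf_bin_width=cfg.maf_bin_width,
        n_sets=cfg.n_null_sets,
        masked_region=None,  # single synthetic chromosome
        seed=seed,
    )
    rec = run_overlap_enrichment(target_p, ref_p, control_p, gm, oc)
    with open(os.path.join(outdir, "ld_enrichment.tsv"), "w") as fh:
        for line in _provenance(cfg, "enrich-ld"):
            fh.write(f"# {line}\n")
        fh.write("field\tvalue\n")
        for k, v in asdict(rec).items():
            fh.write(f"{k}\t{v}\n")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "scan-meqtl": lambda o, c: _scan_stage(o, c, "meqtl"),
    "scan-eqtl": lambda o, c: _scan_stage(o, c, "eqtl"),
    "correlate": _stage_correlate,
    "enrich-annotation": _stage_enrich_annotation,
    "enrich-ld": _stage_enrich_ld,
}

_STAGE_INPUTS = {
    "simulate": [],
    "qc": ["genotypes.tsv"],
    "scan-meqtl": ["genotypes_qc.tsv", "methylation.tsv", "covariates.tsv"],
    "scan-eqtl": ["genotypes_qc.tsv", "expression.tsv", "covariates.tsv"],
    "correlate": ["methylation.tsv", "expression.tsv", "meqtl.tsv", "eqtl.tsv"],
    "enrich-annotation": ["methylation.tsv", "meqtl.tsv"],
    "enrich-ld": ["genotypes_qc.tsv", "meqtl_snp_stats.tsv"],
}


def run_pipeline(config: RunConfig | dict | None, outdir: str) -> dict:
    """Execute the configured stages in dependency order and write a
    manifest of output-file SHA256 digests; returns the manifest dict."""
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    os.makedirs(outdir, exist_ok=True)
    ordered = [s for s in STAGES if s in cfg.stages]
    for stage in ordered:
        for dep in _STAGE_INPUTS[stage]:
            if not os.path.exists(os.path.join(outdir, dep)):
                raise FileNotFoundError(
                    f"stage {stage!r} requires {dep!r}; run its producer first"
                )
        _STAGE_FUNCS[stage](outdir, cfg)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True).encode()
        ).hexdigest(),
        "files": {},
    }
    for name in sorted(os.listdir(outdir)):
        path = os.path.join(outdir, name)
        if name == "manifest.json" or not os.path.isfile(path):
            continue
        with open(path, "rb") as fh:
            manifest["files"][name] = hashlib.sha256(fh.read()).hexdigest()
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
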