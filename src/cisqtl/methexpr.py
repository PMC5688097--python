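"""Cis correlation of CpG methylation with transcript expression on
confounder residuals, plus shared-genetic-driver detection.

The correlation window anchors on the expression probe (the transcript's
5'-TSS), not the CpG. A "shared driver" is declared when a significantly
correlated CpG-transcript pair is both a meQTL and an eQTL and the two
top SNPs are in close LD (r^2 at or above a threshold, default 0.4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .annot import fisher_enrichment
from .io import GenotypeMatrix, IntervalTrack, ProbeMatrix, QtlRecord
from .ld import MonomorphicError, ld_r2
from .scan import bh_fdr, enumerate_cis_pairs

__all__ = [
    "CorrelationRecord",
    "SharedDriver",
    "correlate_cis",
    "find_shared_drivers",
    "direction_summary",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationRecord:
    cpg_id: str
    expr_probe_id: str
    distance_bp: int
    pearson_r: float
    r_squared: float
    p_value: float
    fdr_significant: bool

    @property
    def direction(self) -> int:
        return int(np.sign(self.pearson_r))


@dataclass
class SharedDriver:
    cpg_id: str
    expr_probe_id: str
    meqtl_snp: str
    eqtl_snp: str
    r2_between_snps: float


def correlate_cis(meth_residuals: ProbeMatrix,
                  expr_residuals: ProbeMatrix,
                  window_bp: int = 500_000,
                  fdr: float = 0.01) -> list[CorrelationRecord]:
    """Pearson correlation of every cis CpG-transcript residual pair.

    Both matrices must be confounder residuals over the same samples;
    the test is a two-sided t-transform of r, BH-corrected over all
    tested pairs. Zero-variance vectors are skipped with a log entry.
    """
    if list(meth_residuals.samples) != list(expr_residuals.samples):
        raise ValueError("sample sets/order differ between matrices")
    n = meth_residuals.n_samples
    # window anchored on the expression probe: treat CpGs as the "snps"
    pairs = enumerate_cis_pairs(
        [_as_anchor(p) for p in meth_residuals.probes],
        expr_residuals.probes,
        window_bp,
    )
    M = meth_residuals.values
    E = expr_residuals.values
    records: list[CorrelationRecord] = []
    kept_pairs = []
    rs = []
    for ci, ej in pairs:
        x = M[:, ci]
        y = E[:, ej]
        if x.std() == 0 or y.std() == 0:
            logger.info("skipping zero-variance pair (%s, %s)",
                        meth_residuals.probes[ci].probe_id,
                        expr_residuals.probes[ej].probe_id)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        kept_pairs.append((ci, ej))
        rs.append(r)
    rs = np.array(rs)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rs * np.sqrt(df / np.maximum(1.0 - rs**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.maximum(p, np.finfo(float).tiny)
    flags, _ = bh_fdr(p, fdr)
    for k, (ci, ej) in enumerate(kept_pairs):
        records.append(
            CorrelationRecord(
                cpg_id=meth_residuals.probes[ci].probe_id,
                expr_probe_id=expr_residuals.probes[ej].probe_id,
                distance_bp=abs(meth_residuals.probes[ci].anchor_pos
                                - expr_residuals.probes[ej].anchor_pos),
                pearson_r=float(rs[k]),
                r_squared=float(rs[k] ** 2),
                p_value=float(p[k]),
                fdr_significant=bool(flags[k]),
            )
        )
    return records


class _Anchor:
    __slots__ = ("chrom", "pos")

    def __init__(self, chrom, pos):
        self.chrom = chrom
        self.pos = pos


def _as_anchor(probe):
    return _Anchor(probe.chrom, probe.anchor_pos)


def top_snp_per_probe(records: list[QtlRecord],
                      genotypes: GenotypeMatrix) -> dict[str, str]:
    """Most significantly associated SNP per probe (smallest p, ties broken
    by smaller genomic position)."""
    idx = genotypes.snp_index()
    best: dict[str, QtlRecord] = {}
    for r in records:
        cur = best.get(r.probe_id)
        key = (r.p_value, genotypes.snps[idx[r.snp_id]].pos)
        if cur is None or key < (cur.p_value, genotypes.snps[idx[cur.snp_id]].pos):
            best[r.probe_id] = r
    return {probe: rec.snp_id for probe, rec in best.items()}


def find_shared_drivers(meqtl_records: list[QtlRecord],
                        eqtl_records: list[QtlRecord],
                        correlation_records: list[CorrelationRecord],
                        genotypes: GenotypeMatrix,
                        r2_min: float = 0.4) -> list[SharedDriver]:
    """For each significant correlation whose CpG is a meQTL and whose
    transcript is an eQTL, emit the pair when the two top SNPs are in LD
    (r^2 >= r2_min)."""
    top_me = top_snp_per_probe(
        [r for r in meqtl_records if r.fdr_significant], genotypes)
    top_e = top_snp_per_probe(
        [r for r in eqtl_records if r.fdr_significant], genotypes)
    drivers: list[SharedDriver] = []
    for rec in correlation_records:
        if not rec.fdr_significant:
            continue
        snp_m = top_me.get(rec.cpg_id)
        snp_e = top_e.get(rec.expr_probe_id)
        if snp_m is None or snp_e is None:
            continue
        try:
            r2 = ld_r2(genotypes.column(snp_m), genotypes.column(snp_e))
        except MonomorphicError:
            logger.info("top SNP monomorphic for pair (%s, %s); skipped",
                        rec.cpg_id, rec.expr_probe_id)
            continue
        if r2 >= r2_min:
            drivers.append(
                SharedDriver(cpg_id=rec.cpg_id, expr_probe_id=rec.expr_probe_id,
                             meqtl_snp=snp_m, eqtl_snp=snp_e,
                             r2_between_snps=float(r2))
            )
    return drivers


def direction_summary(correlation_records: list[CorrelationRecord],
                      promoter_track: IntervalTrack,
                      cpg_positions: dict[str, tuple[str, int]]) -> dict:
    """Counts of positive/negative correlations overall and inside/outside
    the promoter track, plus a Fisher odds ratio for (negative direction x
    promoter membership).

    ``cpg_positions`` maps cpg_id -> (chrom, 1-based position).
    """
    recs = [r for r in correlation_records if r.fdr_significant] or correlation_records
    n_neg = sum(1 for r in recs if r.pearson_r < 0)
    n_pos = len(recs) - n_neg
    in_prom = np.array([
        promoter_track.contains(*cpg_positions[r.cpg_id]) for r in recs
    ])
    neg = np.array([r.pearson_r < 0 for r in recs])
    # rows = direction (negative first), columns = promoter membership
    table = (
        int((neg & in_prom).sum()),    # negative, in promoter
        int((neg & ~in_prom).sum()),   # negative, outside
        int((~neg & in_prom).sum()),   # positive, in promoter
        int((~neg & ~in_prom).sum()),  # positive, outside
    )
    out = {
        "n_records": len(recs),
        "n_negative": n_neg,
        "n_positive": n_pos,
        "fraction_negative": n_neg / len(recs) if recs else float("nan"),
        "n_promoter_negative": table[0],
        "n_promoter_positive": table[2],
    }
    if all(m > 0 for m in (table[0] + table[1], table[2] + table[3])):
        fisher = fisher_enrichment(table[0], table[1], table[2], table[3])
        out["odds_ratio"] = fisher.odds_ratio
        out["p_value"] = fisher.p_value
    return out
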