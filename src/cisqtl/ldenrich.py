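"""Clumping-based empirical enrichment of QTL-SNPs against reference SNP
sets (other QTL catalogs or GWAS hit lists).

Workflow: clump the target QTL-SNP set and the reference set to
quasi-independent index SNPs (r^2 < 0.25 within 250 kb, keeping the most
significant SNP), optionally exclude a masked region, count target SNPs
in LD with at least one reference SNP, then build an empirical null
from MAF-matched control sets drawn from clumped non-QTL SNPs. The
enrichment statistic is observed overlap divided by the null mean, and
the empirical p-value is the fraction of control sets reaching the
observed count (reported as an upper bound 1/n_sets when none do).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix, SnpAnnotation
from .ld import clump, maf_matched_sets

__all__ = [
    "EmpiricalEnrichment",
    "count_ld_overlap",
    "empirical_enrichment",
    "exclude_region",
    "run_overlap_enrichment",
    "OverlapConfig",
]

MHC_DEFAULT = ("chr6", 2_500_000, 3_500_000)  # as printed; configurable


@dataclass
class EmpiricalEnrichment:
    n_target_clumped: int
    n_reference_clumped: int
    observed_overlap: int
    null_mean: float
    null_sd: float
    error_of_mean: float
    enrichment: float
    empirical_p: float
    n_sets: int
    p_is_upper_bound: bool = False  # True when no null set reached the observed count

    @classmethod
    def from_null_counts(cls, observed: int, null_counts: np.ndarray,
                         n_target_clumped: int = 0, n_reference_clumped: int = 0,
                         conservative_p: bool = False) -> "EmpiricalEnrichment":
        null_counts = np.asarray(null_counts, dtype=float)
        n_sets = len(null_counts)
        mean = float(null_counts.mean())
        sd = float(null_counts.std(ddof=1)) if n_sets > 1 else 0.0
        k = int((null_counts >= observed).sum())
        if conservative_p:
            p = (k + 1) / (n_sets + 1)
            upper = False
        else:
            p = k / n_sets if k > 0 else 1.0 / n_sets
            upper = k == 0
        return cls(
            n_target_clumped=n_target_clumped,
            n_reference_clumped=n_reference_clumped,
            observed_overlap=observed,
            null_mean=mean,
            null_sd=sd,
            error_of_mean=sd / np.sqrt(n_sets) if n_sets else float("nan"),
            enrichment=observed / mean if mean > 0 else float("nan"),
            empirical_p=float(p),
            n_sets=n_sets,
            p_is_upper_bound=upper,
        )

    @classmethod
    def from_summary(cls, observed: int, null_mean: float, null_sd: float = 0.0,
                     n_sets: int = 0, n_target_clumped: int = 0,
                     n_reference_clumped: int = 0) -> "EmpiricalEnrichment":
        """Build the record from published/worked-example summary inputs."""
        return cls(
            n_target_clumped=n_target_clumped,
            n_reference_clumped=n_reference_clumped,
            observed_overlap=observed,
            null_mean=null_mean,
            null_sd=null_sd,
            error_of_mean=(null_sd / np.sqrt(n_sets)) if n_sets else float("nan"),
            enrichment=observed / null_mean if null_mean > 0 else float("nan"),
            empirical_p=float("nan"),
            n_sets=n_sets,
        )


def count_ld_overlap(set_a: list[str], set_b: list[str],
                     genotypes: GenotypeMatrix,
                     r2_min: float = 0.25,
                     window_bp: int = 250_000) -> int:
    """Number of SNPs in A with >=1 SNP in B at r^2 >= r2_min within
    window_bp. A SNP present in both sets counts (r^2 with itself = 1)."""
    idx = genotypes.snp_index()
    missing = [s for s in list(set_a) + list(set_b) if s not in idx]
    if missing:
        raise KeyError(f"SNPs absent from genotypes: {sorted(set(missing))[:5]}")
    return int(_overlap_flags(list(set_a), list(set_b), genotypes, r2_min,
                              window_bp).sum())


def _overlap_flags(set_a: list[str], set_b: list[str],
                   genotypes: GenotypeMatrix,
                   r2_min: float, window_bp: int) -> np.ndarray:
    """Boolean per SNP in set_a: has an LD partner in set_b."""
    idx = genotypes.snp_index()
    b_idx = [idx[s] for s in set_b]
    b_pos = np.array([genotypes.snps[j].pos for j in b_idx])
    b_chrom = np.array([genotypes.snps[j].chrom for j in b_idx])
    order = np.argsort(b_pos, kind="mergesort")
    b_pos, b_chrom = b_pos[order], b_chrom[order]
    b_cols = genotypes.dosage[:, [b_idx[k] for k in order]].copy()
    for j in range(b_cols.shape[1]):
        m = np.isnan(b_cols[:, j])
        if m.any():
            b_cols[m, j] = np.nanmean(b_cols[:, j])
    b_set = set(set_b)
    flags = np.zeros(len(set_a), dtype=bool)
    for i, sid in enumerate(set_a):
        if sid in b_set:
            flags[i] = True
            continue
        j = idx[sid]
        snp = genotypes.snps[j]
        lo = np.searchsorted(b_pos, snp.pos - window_bp, side="left")
        hi = np.searchsorted(b_pos, snp.pos + window_bp, side="right")
        if hi <= lo:
            continue
        cand = np.arange(lo, hi)[b_chrom[lo:hi] == snp.chrom]
        if cand.size == 0:
            continue
        a_col = genotypes.dosage[:, j].copy()
        m = np.isnan(a_col)
        if m.any():
            a_col[m] = np.nanmean(a_col)
        if a_col.std() == 0:
            continue
        B = b_cols[:, cand]
        Bc = B - B.mean(axis=0, keepdims=True)
        ac = a_col - a_col.mean()
        denom = np.sqrt((Bc**2).sum(axis=0) * (ac**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Bc.T @ ac) / denom
        if np.nanmax(r**2, initial=0.0) >= r2_min:
            flags[i] = True
    return flags


def empirical_enrichment(observed: int,
                         target_snps: list[SnpAnnotation],
                         control_pool: list[SnpAnnotation],
                         reference_set: list[str],
                         genotypes: GenotypeMatrix,
                         n_sets: int = 10_000,
                         seed: int = 0,
                         r2_min: float = 0.25,
                         window_bp: int = 250_000,
                         maf_bin_width: float = 0.02,
                         conservative_p: bool = False) -> EmpiricalEnrichment:
    """Empirical null for an observed LD-overlap count.

    Draws ``n_sets`` MAF-matched control sets from ``control_pool`` and
    counts, per set, how many control SNPs are in LD with the reference
    set. Pool overlap flags are precomputed once, so the per-set cost is
    a binned draw plus a sum.
    """
    if n_sets < 100:
        raise ValueError("n_sets must be >= 100 for a usable null")
    pool_ids = [s.snp_id for s in control_pool]
    pool_flags = dict(zip(pool_ids, _overlap_flags(pool_ids, reference_set,
                                                   genotypes, r2_min, window_bp)))
    sets = maf_matched_sets(control_pool, target_snps, n_sets,
                            maf_bin_width=maf_bin_width, seed=seed)
    null_counts = np.array([sum(pool_flags[s] for s in chosen) for chosen in sets])
    rec = EmpiricalEnrichment.from_null_counts(
        observed, null_counts,
        n_target_clumped=len(target_snps),
        n_reference_clumped=len(reference_set),
        conservative_p=conservative_p,
    )
    if rec.null_mean == 0:
        rec.enrichment = float("nan")
    return rec


def exclude_region(snps: list[SnpAnnotation], chrom: str,
                   start: int, end: int) -> list[SnpAnnotation]:
    """Drop SNPs inside the 1-based inclusive interval [start, end] on chrom."""
    return [s for s in snps
            if not (s.chrom == chrom and start <= s.pos <= end)]


@dataclass
class OverlapConfig:
    clump_r2: float = 0.25
    clump_window_bp: int = 250_000
    overlap_r2: float = 0.25
    overlap_window_bp: int = 250_000  # 1 Mb for the eQTL-vs-meQTL comparison
    n_sets: int = 10_000
    maf_bin_width: float = 0.02
    masked_region: tuple[str, int, int] | None = MHC_DEFAULT
    seed: int = 0


def run_overlap_enrichment(target_pvalues: dict[str, float],
                           reference_pvalues: dict[str, float],
                           control_pvalues: dict[str, float],
                           genotypes: GenotypeMatrix,
                           config: OverlapConfig) -> EmpiricalEnrichment:
    """End-to-end enrichment: clump target, reference and control pool,
    mask the excluded region, count LD overlap, simulate the null.

    ``control_pvalues`` covers the non-QTL pool (e.g. SNPs with FDR > 10%
    in the scan); it is clumped with the same parameters as the target.
    """
    idx = genotypes.snp_index()

    def _clumped(pvals: dict[str, float]) -> list[SnpAnnotation]:
        res = clump(pvals, genotypes, r2_min=config.clump_r2,
                    window_bp=config.clump_window_bp)
        snps = res.index_snps
        if config.masked_region is not None:
            snps = exclude_region(snps, *config.masked_region)
        return snps

    target = _clumped(target_pvalues)
    reference = _clumped(reference_pvalues)
    pool = _clumped(control_pvalues)
    pool = [s for s in pool if s.snp_id not in target_pvalues]
    ref_ids = [s.snp_id for s in reference]
    observed = count_ld_overlap([s.snp_id for s in target], ref_ids, genotypes,
                                r2_min=config.overlap_r2,
                                window_bp=config.overlap_window_bp)
    rec = empirical_enrichment(
        observed,
        target_snps=target,
        control_pool=pool,
        reference_set=ref_ids,
        genotypes=genotypes,
        n_sets=config.n_sets,
        seed=config.seed,
        r2_min=config.overlap_r2,
        window_bp=config.overlap_window_bp,
        maf_bin_width=config.maf_bin_width,
    )
    rec.n_target_clumped = len(target)
    rec.n_reference_clumped = len(reference)
    return rec
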