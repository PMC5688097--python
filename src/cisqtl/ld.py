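"""Linkage-disequilibrium primitives: r^2, greedy pruning, p-value-driven
clumping, and MAF-matched control-set sampling.

r^2 is the squared Pearson correlation of (unphased) dosage vectors —
composite LD, matching PLINK's default on genotype data. Clumping
iteratively takes the most significant unassigned SNP as an index and
absorbs every unassigned SNP within the window that has r^2 at or above
the threshold, so index SNPs are mutually quasi-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix, SnpAnnotation

__all__ = ["ClumpResult", "ld_r2", "ld_prune", "clump", "maf_matched_sets"]


class MonomorphicError(ValueError):
    """LD is undefined for a monomorphic dosage vector."""


@dataclass
class ClumpResult:
    index_snps: list[SnpAnnotation]  # ascending p
    members: dict[str, list[str]]  # index snp_id -> clumped-away snp_ids
    r2_threshold: float
    window_bp: int

    @property
    def index_ids(self) -> list[str]:
        return [s.snp_id for s in self.index_snps]

    def all_snp_ids(self) -> set[str]:
        out = set(self.index_ids)
        for mem in self.members.values():
            out.update(mem)
        return out


def _impute_mean(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    m = np.isnan(v)
    if m.any():
        v = v.copy()
        v[m] = np.nanmean(v)
    return v


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD)."""
    a = _impute_mean(dosage_a)
    b = _impute_mean(dosage_b)
    if len(a) != len(b):
        raise ValueError("dosage vectors must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise MonomorphicError("LD undefined for a monomorphic SNP")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _r2_matrix_vs(genos: np.ndarray, col: np.ndarray) -> np.ndarray:
    """r^2 of each column of ``genos`` with ``col`` (columns mean-imputed)."""
    X = genos - genos.mean(axis=0, keepdims=True)
    y = col - col.mean()
    denom = np.sqrt((X**2).sum(axis=0) * (y**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (X.T @ y) / denom
    return r**2


def ld_prune(genotypes: GenotypeMatrix, r2_max: float = 0.8,
             window_snps: int = 50) -> list[int]:
    """Greedy left-to-right pruning.

    A SNP is dropped when its r^2 with any of the previous
    ``window_snps`` retained SNPs reaches ``r2_max``; returns indices of
    kept SNPs in input (position) order.
    """
    kept: list[int] = []
    cols: list[np.ndarray] = []
    for j in range(genotypes.n_snps):
        col = _impute_mean(genotypes.dosage[:, j])
        if col.std() == 0:
            continue  # monomorphic columns carry no LD information
        drop = False
        for prev in cols[-window_snps:]:
            r = np.corrcoef(prev, col)[0, 1]
            if r * r >= r2_max:
                drop = True
                break
        if not drop:
            kept.append(j)
            cols.append(col)
    return kept


def clump(snp_pvalues: dict[str, float],
          genotypes: GenotypeMatrix,
          r2_min: float = 0.25,
          window_bp: int = 250_000) -> ClumpResult:
    """PLINK-style clumping: repeatedly index the smallest-p unassigned SNP
    (ties broken by genomic position) and absorb unassigned SNPs with
    r^2 >= r2_min within window_bp."""
    idx_map = genotypes.snp_index()
    missing = [s for s in snp_pvalues if s not in idx_map]
    if missing:
        raise KeyError(f"SNPs absent from genotypes: {', '.join(missing[:5])}")
    order = sorted(
        snp_pvalues,
        key=lambda s: (snp_pvalues[s], genotypes.snps[idx_map[s]].pos, s),
    )
    dosage = np.column_stack(
        [_impute_mean(genotypes.dosage[:, idx_map[s]]) for s in order]
    )
    pos = np.array([genotypes.snps[idx_map[s]].pos for s in order])
    chrom = np.array([genotypes.snps[idx_map[s]].chrom for s in order])
    n = len(order)
    assigned = np.zeros(n, dtype=bool)
    index_snps: list[SnpAnnotation] = []
    members: dict[str, list[str]] = {}
    for i in range(n):
        if assigned[i]:
            continue
        assigned[i] = True
        snp = genotypes.snps[idx_map[order[i]]]
        index_snps.append(snp)
        cand = np.where(
            (~assigned)
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window_bp)
        )[0]
        mem: list[str] = []
        if len(cand):
            r2 = _r2_matrix_vs(dosage[:, cand], dosage[:, i])
            hit = cand[np.nan_to_num(r2) >= r2_min]
            assigned[hit] = True
            mem = [order[j] for j in hit]
        members[snp.snp_id] = mem
    return ClumpResult(index_snps=index_snps, members=members,
                       r2_threshold=r2_min, window_bp=window_bp)


def maf_matched_sets(control_pool: list[SnpAnnotation],
                     target_snps: list[SnpAnnotation],
                     n_sets: int,
                     maf_bin_width: float = 0.02,
                     seed: int = 0) -> list[list[str]]:
    """Random control-SNP sets matching the target's per-MAF-bin counts.

    Sampling is without replacement within a set and independent across
    sets; raises if any bin's pool is smaller than the target count."""
    pool_ids = {s.snp_id for s in control_pool}
    overlap = pool_ids & {s.snp_id for s in target_snps}
    if overlap:
        raise ValueError(f"control pool overlaps targets: {sorted(overlap)[:5]}")

    def bin_of(maf: float) -> int:
        # bins over (0, 0.5]; upper edge inclusive in the last bin
        b = int(np.floor(maf / maf_bin_width))
        return min(b, int(np.ceil(0.5 / maf_bin_width)) - 1)

    target_bins: dict[int, int] = {}
    for s in target_snps:
        target_bins[bin_of(s.maf)] = target_bins.get(bin_of(s.maf), 0) + 1
    pool_by_bin: dict[int, list[str]] = {}
    for s in control_pool:
        pool_by_bin.setdefault(bin_of(s.maf), []).append(s.snp_id)
    for b, need in target_bins.items():
        have = len(pool_by_bin.get(b, []))
        if have < need:
            lo, hi = b * maf_bin_width, (b + 1) * maf_bin_width
            raise ValueError(
                f"MAF bin [{lo:.2f}, {hi:.2f}): need {need} controls, pool has {have}"
            )
    rng = np.random.default_rng(seed)
    sets: list[list[str]] = []
    for _ in range(n_sets):
        chosen: list[str] = []
        for b, need in sorted(target_bins.items()):
            ids = pool_by_bin[b]
            pick = rng.choice(len(ids), size=need, replace=False)
            chosen.extend(ids[k] for k in pick)
        sets.append(chosen)
    return sets
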