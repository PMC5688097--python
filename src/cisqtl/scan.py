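"""Cis-QTL scan: pair enumeration, additive linear model with covariates,
joint Benjamini-Hochberg FDR, and per-term variance decomposition.

The scan regresses each probe on each cis SNP's additive dosage together
with fixed covariate columns (known confounders, genotype PCs, optional
control-probe PCs, and hidden-confounder PCs computed once from
confounder residuals and then frozen — a two-pass design). All cis
pairs of a scan enter a single BH step-up, so the scan reports one
data-dependent p-value threshold.

Per-pair statistics are computed by the Frisch-Waugh-Lovell
decomposition (residualize probe values and dosages on the covariate
design once, then work with residual cross-products), which is
algebraically identical to refitting the full OLS model for every pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CovariateTable, GenotypeMatrix, ProbeMatrix, QtlRecord

__all__ = [
    "ScanConfig",
    "ScanSummary",
    "enumerate_cis_pairs",
    "compute_genotype_pcs",
    "residualize",
    "hidden_confounder_pcs",
    "fit_additive_model",
    "bh_fdr",
    "variance_decomposition",
    "run_cis_scan",
]

logger = logging.getLogger(__name__)

KNOWN_CONFOUNDERS = ("neuronal_proportion", "age_years", "gender")


class AlignmentError(ValueError):
    """Sample sets/order differ between inputs."""


@dataclass
class ScanConfig:
    window_bp: int = 500_000
    fdr_level: float = 0.01
    known_covariates: tuple[str, ...] = KNOWN_CONFOUNDERS
    n_genotype_pcs: int = 3
    n_hidden_pcs: int = 3  # 3 for methylation, 2 for expression
    n_control_probe_pcs: int = 0  # 6 for methylation when control probes supplied

    def __post_init__(self):
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must lie in (0, 1)")


@dataclass
class ScanSummary:
    n_pairs_tested: int
    n_significant_pairs: int
    n_significant_probes: int
    p_threshold: float
    median_abs_beta_top: float
    median_distance_top: float
    n_skipped_monomorphic: int = 0


def enumerate_cis_pairs(snp_ann, probe_ann, window_bp: int) -> list[tuple[int, int]]:
    """All (snp_index, probe_index) pairs on the same chromosome with
    |snp.pos - probe.anchor_pos| <= window_bp (inclusive boundary).

    Sorted-sweep implementation: SNP positions are sorted per chromosome
    and each probe's window is located by bisection, so no all-pairs
    scan is performed.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, s in enumerate(snp_ann):
        by_chrom.setdefault(s.chrom, []).append((s.pos, i))
    sorted_snps = {
        c: (np.array([p for p, _ in sorted(v)]), [i for _, i in sorted(v)])
        for c, v in by_chrom.items()
    }
    pairs: list[tuple[int, int]] = []
    for j, probe in enumerate(probe_ann):
        entry = sorted_snps.get(probe.chrom)
        if entry is None:
            continue
        pos, idx = entry
        lo = np.searchsorted(pos, probe.anchor_pos - window_bp, side="left")
        hi = np.searchsorted(pos, probe.anchor_pos + window_bp, side="right")
        pairs.extend((idx[k], j) for k in range(lo, hi))
    return pairs


def compute_genotype_pcs(genotypes: GenotypeMatrix, n_pcs: int = 3) -> np.ndarray:
    """PCA of the dosage matrix with each SNP column centered and scaled
    by sqrt(2 p (1 - p)), p = alt-allele frequency; returns score vectors."""
    X = genotypes.dosage.copy()
    for j in range(X.shape[1]):
        m = np.isnan(X[:, j])
        if m.any():
            X[m, j] = np.nanmean(X[:, j])
    p = X.mean(axis=0) / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    poly = sd > 0
    if poly.sum() == 0:
        raise ValueError("no polymorphic SNPs for genotype PCA")
    Xs = (X[:, poly] - 2.0 * p[poly]) / sd[poly]
    if min(Xs.shape) < n_pcs:
        raise ValueError("degenerate matrix: fewer dimensions than requested PCs")
    u, s, _ = np.linalg.svd(Xs, full_matrices=False)
    return u[:, :n_pcs] * s[:n_pcs]


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None or covariates.size == 0:
        return np.ones((n, 1))
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != n:
        C = C.T
    return np.column_stack([np.ones(n), C])


def _check_full_rank(X: np.ndarray, names: list[str] | None = None):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via rank-revealing QR on the diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = np.where(diag < tol)[0]
        labels = (
            [names[k] for k in bad] if names is not None else [str(k) for k in bad]
        )
        raise ValueError(f"rank-deficient design; collinear columns: {labels}")


def residualize(matrix: ProbeMatrix | np.ndarray,
                covariates: np.ndarray,
                column_names: list[str] | None = None):
    """Per probe, subtract the least-squares projection on [1, covariates]."""
    values = matrix.values if isinstance(matrix, ProbeMatrix) else np.asarray(matrix, float)
    n = values.shape[0]
    X = _design(covariates, n)
    names = ["intercept"] + (column_names or [f"c{k}" for k in range(X.shape[1] - 1)])
    _check_full_rank(X, names)
    Q, _ = np.linalg.qr(X)
    resid = values - Q @ (Q.T @ values)
    if isinstance(matrix, ProbeMatrix):
        return ProbeMatrix(samples=list(matrix.samples), probes=list(matrix.probes),
                           values=resid, value_kind="residual")
    return resid


def hidden_confounder_pcs(residual_matrix: ProbeMatrix | np.ndarray,
                          n_pcs: int) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores of the samples x probes residual matrix; returns
    (scores, variance proportions), components ordered by variance."""
    values = (residual_matrix.values if isinstance(residual_matrix, ProbeMatrix)
              else np.asarray(residual_matrix, float))
    if np.isnan(values).any():
        raise ValueError("residual matrix must be complete")
    Xc = values - values.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s.max() * max(Xc.shape) * np.finfo(float).eps).sum()) if s.size else 0
    if n_pcs > rank:
        raise ValueError(f"requested {n_pcs} PCs but residual rank is {rank}")
    var = s**2
    props = var / var.sum()
    return u[:, :n_pcs] * s[:n_pcs], props[:n_pcs]


def fit_additive_model(y: np.ndarray, dosage: np.ndarray,
                       covariate_matrix: np.ndarray | None = None):
    """OLS of y on [intercept, dosage, covariates].

    Returns (beta, se, t, p) for the dosage term, with t on n - k degrees
    of freedom and a two-sided p-value.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(dosage, dtype=float)
    m = np.isnan(g)
    if m.any():
        g = g.copy()
        g[m] = np.nanmean(g)
    if g.std() == 0:
        raise ValueError("monomorphic dosage")
    n = len(y)
    base = _design(covariate_matrix, n)
    X = np.column_stack([base[:, :1], g, base[:, 1:]])
    k = X.shape[1]
    if n <= k + 1:
        raise ValueError(f"need n > {k + 1} samples for {k} predictors")
    _check_full_rank(X)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - k
    sigma2 = resid @ resid / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    beta = float(coef[1])
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return beta, se, float(t), float(max(p, np.finfo(float).tiny))


def bh_fdr(p_values: np.ndarray, level: float = 0.01) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up over all supplied p-values jointly.

    Returns (boolean flags, p_threshold) where p_threshold is the largest
    rejected p (0.0 when nothing is rejected).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    crit = level * (np.arange(1, m + 1) / m)
    below = np.where(ranked <= crit)[0]
    if below.size == 0:
        return np.zeros(m, dtype=bool), 0.0
    k = below[-1]
    threshold = float(ranked[k])
    return p <= threshold, threshold


def variance_decomposition(y: np.ndarray, dosage: np.ndarray,
                           covariates: dict[str, np.ndarray]) -> dict[str, float]:
    """Leave-one-term-out ΔR² shares.

    For each term T (genotype or a covariate), share(T) = R²(full) -
    R²(model without T), computed by refitting; negative refit
    differences arising from non-orthogonality are clipped to 0.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(dosage, dtype=float)
    names = list(covariates)
    C = np.column_stack([covariates[k] for k in names]) if names else None

    def r2_of(design_cols: list[np.ndarray]) -> float:
        X = np.column_stack([np.ones(len(y))] + design_cols)
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        sst = ((y - y.mean()) ** 2).sum()
        return 1.0 - resid @ resid / sst if sst > 0 else 0.0

    full_cols = [g] + ([C[:, k] for k in range(C.shape[1])] if C is not None else [])
    r2_full = r2_of(full_cols)
    shares = {"genotype": max(0.0, r2_full - r2_of(full_cols[1:]))}
    for i, name in enumerate(names):
        reduced = [g] + [C[:, k] for k in range(C.shape[1]) if k != i]
        shares[name] = max(0.0, r2_full - r2_of(reduced))
    return shares


def _align_check(genotypes: GenotypeMatrix, probe_matrix: ProbeMatrix,
                 covariates: CovariateTable | None):
    if list(genotypes.samples) != list(probe_matrix.samples):
        raise AlignmentError("genotype and probe samples differ (order matters)")
    if covariates is not None and list(covariates.samples) != list(genotypes.samples):
        raise AlignmentError("covariate samples differ from genotype samples")


def run_cis_scan(genotypes: GenotypeMatrix,
                 probe_matrix: ProbeMatrix,
                 covariates: CovariateTable | None,
                 config: ScanConfig,
                 control_probe_scores: np.ndarray | None = None,
                 keep: str = "significant") -> tuple[list[QtlRecord], ScanSummary]:
    """Scan every cis SNP-probe pair, flag significance by joint BH-FDR.

    ``keep`` controls which records are materialised: "significant"
    (default, mirrors the supplementary-table layout) or "all". The
    summary always covers the complete scan. Variance-decomposition
    fields are filled for the kept records.
    """
    _align_check(genotypes, probe_matrix, covariates)
    n = genotypes.n_samples
    values = probe_matrix.values
    if np.isnan(values).any():
        # probe values mean-imputed for the linear algebra; QC should
        # have removed high-missingness probes upstream
        values = values.copy()
        col_mean = np.nanmean(values, axis=0)
        nan_r, nan_c = np.where(np.isnan(values))
        values[nan_r, nan_c] = col_mean[nan_c]

    # --- covariate assembly (two-pass: hidden PCs frozen from residuals)
    cov_cols: list[np.ndarray] = []
    cov_names: list[str] = []
    known: np.ndarray | None = None
    if covariates is not None and config.known_covariates:
        present = [c for c in config.known_covariates if c in covariates.columns]
        if present:
            known = covariates.matrix(present)
            cov_cols.extend(known.T)
            cov_names.extend(present)
    if config.n_genotype_pcs > 0:
        gpcs = compute_genotype_pcs(genotypes, config.n_genotype_pcs)
        cov_cols.extend(gpcs.T)
        cov_names.extend(f"geno_pc{k+1}" for k in range(gpcs.shape[1]))
    if config.n_control_probe_pcs > 0:
        if control_probe_scores is None:
            raise ValueError("control_probe_scores required when n_control_probe_pcs > 0")
        cp = control_probe_scores[:, : config.n_control_probe_pcs]
        cov_cols.extend(cp.T)
        cov_names.extend(f"control_pc{k+1}" for k in range(cp.shape[1]))
    if config.n_hidden_pcs > 0:
        base = known if known is not None else np.empty((n, 0))
        resid0 = residualize(values, base)
        hpcs, _ = hidden_confounder_pcs(resid0, config.n_hidden_pcs)
        cov_cols.extend(hpcs.T)
        cov_names.extend(f"hidden_pc{k+1}" for k in range(hpcs.shape[1]))
    C = np.column_stack(cov_cols) if cov_cols else None

    # --- FWL residualization
    X = _design(C, n)
    _check_full_rank(X, ["intercept"] + cov_names)
    k_cov = X.shape[1]
    Q, _ = np.linalg.qr(X)

    G = genotypes.dosage.copy()
    for j in range(G.shape[1]):
        m = np.isnan(G[:, j])
        if m.any():
            G[m, j] = np.nanmean(G[:, j])
    mono = G.std(axis=0) == 0
    Gres = G - Q @ (Q.T @ G)
    Yres = values - Q @ (Q.T @ values)

    all_pairs = enumerate_cis_pairs(genotypes.snps, probe_matrix.probes, config.window_bp)
    pairs = [(si, pj) for si, pj in all_pairs if not mono[si]]
    n_mono_skipped = len(all_pairs) - len(pairs)
    if n_mono_skipped:
        logger.info("skipped %d cis pairs with monomorphic dosage", n_mono_skipped)
    if not pairs:
        summary = ScanSummary(0, 0, 0, 0.0, float("nan"), float("nan"),
                              n_skipped_monomorphic=n_mono_skipped)
        return [], summary

    si_arr = np.array([p[0] for p in pairs])
    pj_arr = np.array([p[1] for p in pairs])
    gg = (Gres**2).sum(axis=0)
    yy = (Yres**2).sum(axis=0)
    gy = np.einsum("ij,ij->j", Gres[:, si_arr], Yres[:, pj_arr])
    df = n - k_cov - 1
    beta = gy / gg[si_arr]
    sse = yy[pj_arr] - gy**2 / gg[si_arr]
    sse = np.maximum(sse, 0.0)
    sigma2 = sse / df
    se = np.sqrt(sigma2 / gg[si_arr])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.maximum(p, np.finfo(float).tiny)

    flags, p_threshold = bh_fdr(p, config.fdr_level)

    # --- summaries over top (most significant) SNP per significant probe
    dist = np.abs(
        np.array([genotypes.snps[si].pos for si in si_arr])
        - np.array([probe_matrix.probes[pj].anchor_pos for pj in pj_arr])
    )
    sig_idx = np.where(flags)[0]
    top_per_probe: dict[int, int] = {}
    for i in sig_idx:
        pj = pj_arr[i]
        best = top_per_probe.get(pj)
        if best is None or (p[i], genotypes.snps[si_arr[i]].pos) < (
            p[best], genotypes.snps[si_arr[best]].pos
        ):
            top_per_probe[pj] = i
    top_idx = np.array(sorted(top_per_probe.values()), dtype=int)
    summary = ScanSummary(
        n_pairs_tested=len(pairs),
        n_significant_pairs=int(flags.sum()),
        n_significant_probes=len(top_per_probe),
        p_threshold=p_threshold,
        median_abs_beta_top=(float(np.median(np.abs(beta[top_idx])))
                             if top_idx.size else float("nan")),
        median_distance_top=(float(np.median(dist[top_idx]))
                             if top_idx.size else float("nan")),
        n_skipped_monomorphic=n_mono_skipped,
    )

    keep_idx = np.arange(len(pairs)) if keep == "all" else sig_idx
    records: list[QtlRecord] = []
    term_cols: dict[str, np.ndarray] = {}
    if covariates is not None:
        for c in ("neuronal_proportion", "age_years", "gender"):
            if c in covariates.columns:
                term_cols[c] = covariates.data[c].to_numpy(dtype=float)
    for i in keep_idx:
        si, pj = int(si_arr[i]), int(pj_arr[i])
        shares = variance_decomposition(values[:, pj], G[:, si], dict(term_cols))
        records.append(
            QtlRecord(
                snp_id=genotypes.snps[si].snp_id,
                probe_id=probe_matrix.probes[pj].probe_id,
                distance_bp=int(dist[i]),
                beta=float(beta[i]),
                se=float(se[i]),
                t_stat=float(t[i]),
                p_value=float(p[i]),
                fdr_significant=bool(flags[i]),
                r2_genotype=shares.get("genotype", np.nan),
                r2_neuronal=shares.get("neuronal_proportion", np.nan),
                r2_age=shares.get("age_years", np.nan),
                r2_gender=shares.get("gender", np.nan),
            )
        )
    return records, summary
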