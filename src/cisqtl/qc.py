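"""SNP and probe quality-control filters plus normalization transforms.

The probe filter cascades attribute each removed probe to the FIRST
failing rule in the documented order, so QC reports are reproducible and
counts are conserved (input = removed + output).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .io import GenotypeMatrix, ProbeMatrix, SnpAnnotation

__all__ = [
    "QcReport",
    "snp_qc",
    "hwe_exact_p",
    "filter_cpg_probes",
    "filter_expression_probes",
    "quantile_normalize",
    "log2_offset_transform",
    "control_probe_pcs",
]


@dataclass
class QcReport:
    stage: str
    n_input: int
    n_removed_per_rule: dict[str, int] = field(default_factory=dict)
    n_output: int = 0

    def validate(self):
        if self.n_input - sum(self.n_removed_per_rule.values()) != self.n_output:
            raise AssertionError("QcReport counts not conserved")
        return self


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test, conditional on allele counts.

    Sums the conditional probabilities of all heterozygote counts whose
    probability does not exceed that of the observed count. Monomorphic
    markers return p = 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa + n_Aa  # minor-ish allele count; symmetry makes choice irrelevant
    n_A = 2 * n_AA + n_Aa
    if n_a == 0 or n_A == 0:
        return 1.0
    rare = min(n_a, n_A)
    # heterozygote count shares parity with the rare allele count
    het_values = np.arange(rare % 2, rare + 1, 2)
    # P(het = h | allele counts) ∝ n! / (nAA! nAa! naa!) * 2^h
    n_rare_hom = (rare - het_values) // 2
    n_common_hom = n - het_values - n_rare_hom
    logp = (
        het_values * np.log(2.0)
        - gammaln(het_values + 1)
        - gammaln(n_rare_hom + 1)
        - gammaln(n_common_hom + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = n_Aa
    p_obs = probs[het_values == obs][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def snp_qc(genotypes: GenotypeMatrix,
           call_rate_min: float = 0.97,
           maf_min: float = 0.05,
           hwe_p_min: float = 1e-6) -> tuple[GenotypeMatrix, QcReport]:
    """Keep a SNP iff call rate > call_rate_min AND MAF > maf_min AND
    HWE exact p > hwe_p_min; removals attributed to the first failing rule."""
    for thr in (call_rate_min, maf_min, hwe_p_min):
        if not 0.0 < thr < 1.0:
            raise ValueError("thresholds must lie in (0, 1)")
    removed = {"call_rate": 0, "maf": 0, "hwe": 0}
    keep = []
    for j in range(genotypes.n_snps):
        col = genotypes.dosage[:, j]
        ok = ~np.isnan(col)
        call_rate = ok.mean() if col.size else 0.0
        if not call_rate > call_rate_min:
            removed["call_rate"] += 1
            continue
        obs = col[ok]
        p = obs.mean() / 2.0
        maf = min(p, 1.0 - p)
        if not maf > maf_min:
            removed["maf"] += 1
            continue
        # HWE needs hard calls; round imputed dosages
        hard = np.rint(obs).astype(int)
        counts = np.bincount(np.clip(hard, 0, 2), minlength=3)
        if not hwe_exact_p(counts[0], counts[1], counts[2]) > hwe_p_min:
            removed["hwe"] += 1
            continue
        keep.append(j)
    if not keep:
        warnings.warn("snp_qc removed every SNP", stacklevel=2)
    report = QcReport(
        stage="snp_qc",
        n_input=genotypes.n_snps,
        n_removed_per_rule=removed,
        n_output=len(keep),
    ).validate()
    return genotypes.subset_snps(keep), report


def filter_cpg_probes(beta_matrix: ProbeMatrix,
                      detection_p: np.ndarray | None = None,
                      bead_counts: np.ndarray | None = None,
                      crosshyb_list: set[str] | None = None,
                      snp_probe_list: set[str] | None = None,
                      snp_annotation: list[SnpAnnotation] | None = None,
                      cis_window: int = 500_000,
                      detection_p_max: float = 0.01,
                      sample_fraction: float = 0.05,
                      bead_count_min: int = 3) -> tuple[ProbeMatrix, QcReport]:
    """Methylation probe filter cascade, first-failing-rule attribution:

    (i)   detection p > 0.01 in >= 5% of samples,
    (ii)  bead count < 3 in >= 5% of samples,
    (iii) probe on the cross-hybridization exclusion list,
    (iv)  probe on the SNP-containing-probe exclusion list,
    (v)   no SNP within +/- cis_window of the CpG (inclusive boundary).
    """
    n_samples = beta_matrix.n_samples
    crosshyb_list = crosshyb_list or set()
    snp_probe_list = snp_probe_list or set()
    if detection_p is not None and detection_p.shape != beta_matrix.values.shape:
        raise ValueError("detection_p shape must match the beta matrix")
    if bead_counts is not None and bead_counts.shape != beta_matrix.values.shape:
        raise ValueError("bead_counts shape must match the beta matrix")
    snp_positions: dict[str, np.ndarray] = {}
    if snp_annotation is not None:
        by_chrom: dict[str, list[int]] = {}
        for s in snp_annotation:
            by_chrom.setdefault(s.chrom, []).append(s.pos)
        snp_positions = {c: np.sort(np.array(v)) for c, v in by_chrom.items()}
    removed = {"detection_p": 0, "bead_count": 0, "crosshyb": 0,
               "snp_probe": 0, "no_cis_snp": 0}
    keep = []
    for j, probe in enumerate(beta_matrix.probes):
        if detection_p is not None:
            frac = np.mean(detection_p[:, j] > detection_p_max)
            if frac >= sample_fraction:
                removed["detection_p"] += 1
                continue
        if bead_counts is not None:
            frac = np.mean(bead_counts[:, j] < bead_count_min)
            if frac >= sample_fraction:
                removed["bead_count"] += 1
                continue
        if probe.probe_id in crosshyb_list:
            removed["crosshyb"] += 1
            continue
        if probe.probe_id in snp_probe_list:
            removed["snp_probe"] += 1
            continue
        if snp_annotation is not None:
            pos = snp_positions.get(probe.chrom)
            if pos is None or not _has_within(pos, probe.anchor_pos, cis_window):
                removed["no_cis_snp"] += 1
                continue
        keep.append(j)
    report = QcReport(
        stage="filter_cpg_probes",
        n_input=beta_matrix.n_probes,
        n_removed_per_rule=removed,
        n_output=len(keep),
    ).validate()
    return beta_matrix.subset_probes(keep), report


def _has_within(sorted_pos: np.ndarray, anchor: int, window: int) -> bool:
    lo = np.searchsorted(sorted_pos, anchor - window, side="left")
    hi = np.searchsorted(sorted_pos, anchor + window, side="right")
    return hi > lo


def filter_expression_probes(expr_matrix: ProbeMatrix,
                             detection_p: np.ndarray | None = None,
                             crosshyb_list: set[str] | None = None,
                             snp_probe_list: set[str] | None = None,
                             detection_p_max: float = 0.05,
                             weak_fraction: float = 0.95) -> tuple[ProbeMatrix, QcReport]:
    """Remove weakly expressed probes (detection p > 0.05 in >= 95% of
    samples) and probes on either exclusion list."""
    crosshyb_list = crosshyb_list or set()
    snp_probe_list = snp_probe_list or set()
    if detection_p is not None and detection_p.shape != expr_matrix.values.shape:
        raise ValueError("detection_p shape must match the expression matrix")
    removed = {"weak_expression": 0, "crosshyb": 0, "snp_probe": 0}
    keep = []
    for j, probe in enumerate(expr_matrix.probes):
        if detection_p is not None:
            if np.mean(detection_p[:, j] > detection_p_max) >= weak_fraction:
                removed["weak_expression"] += 1
                continue
        if probe.probe_id in crosshyb_list:
            removed["crosshyb"] += 1
            continue
        if probe.probe_id in snp_probe_list:
            removed["snp_probe"] += 1
            continue
        keep.append(j)
    report = QcReport(
        stage="filter_expression_probes",
        n_input=expr_matrix.n_probes,
        n_removed_per_rule=removed,
        n_output=len(keep),
    ).validate()
    return expr_matrix.subset_probes(keep), report


def quantile_normalize(matrix: np.ndarray,
                       column_subsets: list[np.ndarray] | None = None) -> np.ndarray:
    """Quantile-normalize samples (rows) to a common distribution within
    each probe subset.

    Within a subset, each sample's values are replaced by the mean
    order statistic across samples at the same rank; tied values receive
    the reference value interpolated at their average rank; missing
    values are excluded from ranking and restored as missing. With a
    single subset this is ordinary whole-matrix quantile normalization.
    """
    from scipy.stats import rankdata

    matrix = np.asarray(matrix, dtype=float)
    out = matrix.copy()
    n_samples, n_probes = matrix.shape
    if column_subsets is None:
        column_subsets = [np.arange(n_probes)]
    covered = np.concatenate([np.asarray(s) for s in column_subsets]) if column_subsets else []
    if len(covered) and (len(np.unique(covered)) != len(covered)):
        raise ValueError("column subsets must be disjoint")
    for subset in column_subsets:
        subset = np.asarray(subset, dtype=int)
        m = len(subset)
        if m < 2:
            warnings.warn("quantile_normalize: subset with < 2 probes left unchanged",
                          stacklevel=2)
            continue
        block = matrix[:, subset]
        grid = np.linspace(0.0, 1.0, m)
        # reference quantile function: mean of per-sample empirical quantiles
        ref = np.zeros(m)
        n_used = 0
        for i in range(n_samples):
            v = block[i]
            obs = ~np.isnan(v)
            k = obs.sum()
            if k == 0:
                continue
            sv = np.sort(v[obs])
            q = np.linspace(0.0, 1.0, k) if k > 1 else np.array([0.5])
            ref += np.interp(grid, q, sv)
            n_used += 1
        if n_used == 0:
            continue
        ref /= n_used
        for i in range(n_samples):
            v = block[i]
            obs = ~np.isnan(v)
            k = obs.sum()
            if k == 0:
                continue
            r = rankdata(v[obs], method="average")
            pos = (r - 1) / (k - 1) if k > 1 else np.full(k, 0.5)
            newv = np.full(m, np.nan)
            newv[obs] = np.interp(pos, grid, ref)
            out[i, subset] = newv
    return out


def log2_offset_transform(expr_matrix: ProbeMatrix, offset: float = 16.0) -> ProbeMatrix:
    """v -> log2(v + offset); raw intensities must exceed -offset."""
    v = expr_matrix.values
    if np.nanmin(v) <= -offset:
        raise ValueError(f"values <= -{offset} cannot be log-transformed")
    return ProbeMatrix(
        samples=list(expr_matrix.samples),
        probes=list(expr_matrix.probes),
        values=np.log2(v + offset),
        value_kind="log2_expression",
    )


def control_probe_pcs(control_matrix: np.ndarray, n_pcs: int = 6):
    """PCA scores of a samples x control-probes intensity matrix.

    Returns (scores, variance_proportions); scores are the first
    ``n_pcs`` principal-component projections after column centering,
    ordered by decreasing explained variance.
    """
    X = np.asarray(control_matrix, dtype=float)
    if np.isnan(X).any():
        raise ValueError("control matrix must be complete")
    n_samples = X.shape[0]
    if n_samples < n_pcs:
        raise ValueError(f"need >= {n_pcs} samples for {n_pcs} PCs")
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    props = var / total if total > 0 else var
    scores = u[:, :n_pcs] * s[:n_pcs]
    return scores, props[:n_pcs]
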