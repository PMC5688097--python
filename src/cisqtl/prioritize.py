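"""Epigenomic profiling of QTL-SNPs: CADD thresholding with best-SNP
selection per probe, CpG creation/abolition calls, TFBS joins, TF
over-representation, and GWAS-catalog matching.

External scores (CADD-Phred, SNP2TFBS predictions, GWAS catalog rows)
are consumed as plain tables; nothing here recomputes them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .annot import EnrichmentRecord, fisher_enrichment
from .io import QtlRecord

__all__ = [
    "PrioritizedSnp",
    "filter_by_cadd",
    "cpg_disruption",
    "join_tfbs",
    "tf_overrepresentation",
    "match_gwas_catalog",
]

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")


@dataclass
class PrioritizedSnp:
    snp_id: str
    probe_id: str
    cadd_phred: float
    is_best_for_probe: bool = False
    cpg_effect: str = "none"  # creates | abolishes | none
    tfbs_hits: list[str] = field(default_factory=list)
    gwas_matches: list[tuple[str, float]] = field(default_factory=list)


def filter_by_cadd(qtl_records: list[QtlRecord],
                   cadd_table: dict[str, float],
                   snp_positions: dict[str, int] | None = None,
                   threshold: float = 5.0) -> list[PrioritizedSnp]:
    """Keep QTL records whose SNP has CADD-Phred strictly above the
    threshold; per probe, mark the record with the maximal score
    (ties broken by smaller p, then smaller genomic position)."""
    n_missing = 0
    kept: list[tuple[QtlRecord, float]] = []
    for rec in qtl_records:
        score = cadd_table.get(rec.snp_id)
        if score is None:
            n_missing += 1
            continue
        if score > threshold:
            kept.append((rec, score))
    if n_missing:
        logger.info("filter_by_cadd: %d records lacked a CADD score", n_missing)
    best_of: dict[str, tuple] = {}
    for rec, score in kept:
        pos = (snp_positions or {}).get(rec.snp_id, 0)
        key = (-score, rec.p_value, pos)
        cur = best_of.get(rec.probe_id)
        if cur is None or key < cur[0]:
            best_of[rec.probe_id] = (key, rec.snp_id)
    out = []
    for rec, score in kept:
        out.append(
            PrioritizedSnp(
                snp_id=rec.snp_id,
                probe_id=rec.probe_id,
                cadd_phred=score,
                is_best_for_probe=best_of[rec.probe_id][1] == rec.snp_id,
            )
        )
    return out


def cpg_disruption(ref_context_triplet: str, ref_allele: str,
                   alt_allele: str) -> str:
    """Classify whether the allele swap creates or abolishes a forward-strand
    CpG dinucleotide in the (left, SNP, right) context.

    The context triplet is (left base, ref allele, right base); callers
    supply reverse-complemented context for minus-strand analyses.
    """
    triplet = ref_context_triplet.upper()
    ref = ref_allele.upper()
    alt = alt_allele.upper()
    if len(triplet) != 3 or any(b not in VALID_BASES for b in triplet):
        raise ValueError(f"invalid context triplet {ref_context_triplet!r}")
    if ref not in VALID_BASES or alt not in VALID_BASES:
        raise ValueError("alleles must be single A/C/G/T bases")
    if triplet[1] != ref:
        raise ValueError("context middle base must equal the reference allele")
    left, _, right = triplet

    def has_cg(allele: str) -> bool:
        return (left + allele) == "CG" or (allele + right) == "CG"

    ref_cg, alt_cg = has_cg(ref), has_cg(alt)
    if ref_cg and not alt_cg:
        return "abolishes"
    if alt_cg and not ref_cg:
        return "creates"
    return "none"


def join_tfbs(snps: list[PrioritizedSnp], tfbs_table: pd.DataFrame) -> list[PrioritizedSnp]:
    """Left-join TFBS predictions (columns snp_id, factor[, delta]) onto
    the SNP records, populating tfbs_hits in place."""
    by_snp: dict[str, list[str]] = {}
    if len(tfbs_table):
        for snp_id, factor in zip(tfbs_table["snp_id"], tfbs_table["factor"]):
            by_snp.setdefault(str(snp_id), []).append(str(factor))
    for rec in snps:
        rec.tfbs_hits = list(by_snp.get(rec.snp_id, []))
    return snps


def tf_overrepresentation(best_snps_tfbs: list[PrioritizedSnp],
                          background_snps_tfbs: list[PrioritizedSnp],
                          factor: str) -> EnrichmentRecord:
    """Fisher 2x2 of (has a site for ``factor``) x (best vs background)."""
    if not background_snps_tfbs:
        raise ValueError("background set is empty")
    a = sum(1 for s in best_snps_tfbs if factor in s.tfbs_hits)
    b = len(best_snps_tfbs) - a
    c = sum(1 for s in background_snps_tfbs if factor in s.tfbs_hits)
    d = len(background_snps_tfbs) - c
    rec = fisher_enrichment(a, b, c, d)
    rec.track_name = factor
    return rec


def match_gwas_catalog(snps: list[PrioritizedSnp],
                       catalog: pd.DataFrame,
                       p_max: float = 5e-8) -> list[PrioritizedSnp]:
    """Attach catalog rows (snp_id, trait, p) matching by exact snp_id with
    catalog p strictly below p_max."""
    by_snp: dict[str, list[tuple[str, float]]] = {}
    if len(catalog):
        for snp_id, trait, p in zip(catalog["snp_id"], catalog["trait"],
                                    catalog["p"]):
            if float(p) < p_max:
                by_snp.setdefault(str(snp_id), []).append((str(trait), float(p)))
    for rec in snps:
        rec.gwas_matches = list(by_snp.get(rec.snp_id, []))
    return snps
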