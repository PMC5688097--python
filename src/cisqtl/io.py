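"""Domain containers and readers/writers for the pipeline's external formats.

Coordinate conventions: SNP and probe positions are 1-based (VCF-style);
BED interval tracks are 0-based half-open and are converted only at the
:func:`read_track` boundary. Genotype dosages are stored as floats in
[0, 2] with ``NaN`` for missing; missing values are never imputed in the
stored matrix (imputation to the column mean happens at analysis time).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "SnpAnnotation",
    "GenotypeMatrix",
    "ProbeAnnotation",
    "ProbeMatrix",
    "CovariateTable",
    "IntervalTrack",
    "GwasSnpList",
    "QtlRecord",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "read_probe_matrix",
    "write_probe_matrix",
    "read_covariates",
    "write_covariates",
    "read_track",
    "write_track",
    "read_gwas_list",
    "write_gwas_list",
    "write_qtl_table",
    "read_qtl_table",
]

QTL_TABLE_COLUMNS = [
    "snp_id",
    "probe_id",
    "distance_bp",
    "beta",
    "se",
    "t",
    "p",
    "fdr_significant",
    "r2_genotype",
    "r2_neuronal",
    "r2_age",
    "r2_gender",
]


class FormatError(ValueError):
    """Malformed input file (carries a line number where possible)."""


@dataclass(frozen=True)
class SnpAnnotation:
    snp_id: str
    chrom: str
    pos: int  # 1-based bp
    ref_allele: str
    alt_allele: str
    maf: float

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1")


@dataclass(frozen=True)
class ProbeAnnotation:
    probe_id: str
    chrom: str
    anchor_pos: int  # CpG coordinate or 5'-TSS, 1-based
    gene_symbol: str | None = None

    def __post_init__(self):
        if self.anchor_pos < 1:
            raise ValueError(f"{self.probe_id}: anchor position must be >= 1")


def _dosage_maf(col: np.ndarray) -> float:
    """Folded allele frequency of a dosage column, ignoring missing."""
    ok = ~np.isnan(col)
    if not ok.any():
        return float("nan")
    p = float(np.mean(col[ok])) / 2.0
    return min(p, 1.0 - p)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive dosage matrix with per-SNP annotation."""

    samples: list[str]
    snps: list[SnpAnnotation]
    dosage: np.ndarray  # (n_samples, n_snps), NaN = missing

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} snps"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate snp_id in genotype matrix")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self) -> dict[str, int]:
        return {s.snp_id: i for i, s in enumerate(self.snps)}

    def maf(self) -> np.ndarray:
        """Empirical folded MAF per SNP column."""
        return np.array([_dosage_maf(self.dosage[:, j]) for j in range(self.n_snps)])

    def column(self, snp_id: str, impute: bool = False) -> np.ndarray:
        j = self.snp_index()[snp_id]
        col = self.dosage[:, j].copy()
        if impute:
            m = np.isnan(col)
            if m.any():
                col[m] = np.nanmean(col)
        return col

    def subset_snps(self, keep: list[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[j] for j in keep],
            dosage=self.dosage[:, keep],
        )


@dataclass
class ProbeMatrix:
    """Samples x probes quantitative values (beta / M / log2 expression / residual)."""

    samples: list[str]
    probes: list[ProbeAnnotation]
    values: np.ndarray
    value_kind: str  # beta | mvalue | log2_expression | residual

    VALID_KINDS = ("beta", "mvalue", "log2_expression", "residual")

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.value_kind not in self.VALID_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.values.shape != (len(self.samples), len(self.probes)):
            raise ValueError("values shape does not match samples x probes")
        ids = [p.probe_id for p in self.probes]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate probe_id")
        if self.value_kind == "beta":
            v = self.values[~np.isnan(self.values)]
            if v.size and (v.min() < 0.0 or v.max() > 1.0):
                raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    def probe_index(self) -> dict[str, int]:
        return {p.probe_id: i for i, p in enumerate(self.probes)}

    def subset_probes(self, keep: list[int] | np.ndarray) -> "ProbeMatrix":
        keep = np.asarray(keep, dtype=int)
        return ProbeMatrix(
            samples=list(self.samples),
            probes=[self.probes[j] for j in keep],
            values=self.values[:, keep],
            value_kind=self.value_kind,
        )


@dataclass
class CovariateTable:
    """Named per-sample covariate columns (gender, age, neuronal proportion, PCs...)."""

    data: pd.DataFrame  # index = sample ids

    def __post_init__(self):
        if self.data.isna().any().any():
            raise ValueError("covariate table contains missing values")
        if "neuronal_proportion" in self.data.columns:
            np_col = self.data["neuronal_proportion"]
            if ((np_col < 0) | (np_col > 1)).any():
                raise ValueError("neuronal_proportion must lie in [0, 1]")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def matrix(self, columns: list[str] | None = None) -> np.ndarray:
        cols = columns if columns is not None else self.columns
        return self.data[cols].to_numpy(dtype=float)

    def with_columns(self, extra: pd.DataFrame) -> "CovariateTable":
        joined = self.data.join(extra, how="left")
        return CovariateTable(joined)


@dataclass
class IntervalTrack:
    """Named set of genomic intervals, 0-based half-open; overlaps allowed."""

    name: str
    intervals: list[tuple[str, int, int]]

    def __post_init__(self):
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"{self.name}: interval {chrom}:{start}-{end} has start >= end")
        self._trees: dict[str, IntervalTree] | None = None

    def _build(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for chrom, start, end in self.intervals:
                trees.setdefault(chrom, IntervalTree()).addi(start, end)
            self._trees = trees
        return self._trees

    def contains(self, chrom: str, pos_1based: int) -> bool:
        """Whether the 1-based coordinate falls inside any interval."""
        tree = self._build().get(chrom)
        return bool(tree is not None and tree[pos_1based - 1])

    def overlaps_span(self, chrom: str, start0: int, end0: int) -> bool:
        """Whether the 0-based half-open span intersects any interval."""
        tree = self._build().get(chrom)
        return bool(tree is not None and tree.overlap(start0, end0))

    def contains_many(self, chroms, positions_1based) -> np.ndarray:
        return np.array(
            [self.contains(c, int(p)) for c, p in zip(chroms, positions_1based)],
            dtype=bool,
        )

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class GwasSnpList:
    """GWAS summary hits: snp_id, chrom, pos, p_value."""

    records: pd.DataFrame

    REQUIRED = ("snp_id", "chrom", "pos", "p_value")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.records.columns:
                raise FormatError(f"GWAS list missing column {col!r}")
        p = self.records["p_value"]
        if ((p <= 0) | (p > 1)).any():
            raise ValueError("GWAS p_value must lie in (0, 1]")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.records["snp_id"])

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class QtlRecord:
    """One SNP-probe association from a cis scan."""

    snp_id: str
    probe_id: str
    distance_bp: int
    beta: float
    se: float
    t_stat: float
    p_value: float
    fdr_significant: bool
    r2_genotype: float = np.nan
    r2_neuronal: float = np.nan
    r2_age: float = np.nan
    r2_gender: float = np.nan


# ---------------------------------------------------------------------------
# Genotypes

def read_genotypes(path: str, format: str = "auto") -> GenotypeMatrix:
    """Read a genotype matrix from VCF (GT or DS) or from the dosage-TSV dialect.

    The dosage TSV dialect: one row per SNP, tab-separated, columns
    ``snp_id chrom pos ref alt`` followed by one column per sample
    (header row holds the sample ids); missing dosages written as ``NA``.
    Multiallelic VCF records are rejected.
    """
    if format == "auto":
        format = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "dosage_tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    snps: list[SnpAnnotation] = []
    cols: list[np.ndarray] = []
    seen: set[str] = set()
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise FormatError(
                f"{path}: record {i + 1} ({var.ID or var.POS}) is multiallelic "
                f"(ALT={','.join(var.ALT)})"
            )
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where((col < 0) | (col > 2), np.nan, col)
        else:
            # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
            gt = np.asarray(var.gt_types)
            col = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        if snp_id in seen:
            raise FormatError(f"{path}: duplicate snp_id {snp_id!r}")
        seen.add(snp_id)
        snps.append(
            SnpAnnotation(
                snp_id=snp_id,
                chrom=var.CHROM,
                pos=var.POS,
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
                maf=_dosage_maf(col),
            )
        )
        cols.append(col)
    dosage = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(samples=samples, snps=snps, dosage=dosage)


def _read_dosage_tsv(path: str) -> GenotypeMatrix:
    fixed = ["snp_id", "chrom", "pos", "ref", "alt"]
    with open(path) as fh:
        header = None
        rows = []
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if header is None:
                header = parts
                if header[: len(fixed)] != fixed:
                    raise FormatError(
                        f"{path}:{lineno}: dosage TSV header must start with "
                        f"{' '.join(fixed)}"
                    )
                continue
            if len(parts) != len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} fields")
            rows.append((lineno, parts))
    if header is None:
        raise FormatError(f"{path}: empty dosage file")
    samples = header[len(fixed):]
    snps: list[SnpAnnotation] = []
    cols: list[np.ndarray] = []
    seen: set[str] = set()
    for lineno, parts in rows:
        snp_id, chrom, pos, ref, alt = parts[: len(fixed)]
        if snp_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate snp_id {snp_id!r}")
        seen.add(snp_id)
        try:
            vals = np.array(
                [np.nan if v == "NA" else float(v) for v in parts[len(fixed):]]
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: unparseable dosage: {exc}") from None
        snps.append(
            SnpAnnotation(
                snp_id=snp_id,
                chrom=chrom,
                pos=int(pos),
                ref_allele=ref,
                alt_allele=alt,
                maf=_dosage_maf(vals),
            )
        )
        cols.append(vals)
    dosage = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(samples=samples, snps=snps, dosage=dosage)


def write_genotypes_tsv(gm: GenotypeMatrix, path: str, header_lines: list[str] | None = None):
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("\t".join(["snp_id", "chrom", "pos", "ref", "alt"] + gm.samples) + "\n")
        for j, snp in enumerate(gm.snps):
            vals = [
                "NA" if np.isnan(v) else format(v, ".6g") for v in gm.dosage[:, j]
            ]
            fh.write(
                "\t".join(
                    [snp.snp_id, snp.chrom, str(snp.pos), snp.ref_allele, snp.alt_allele]
                    + vals
                )
                + "\n"
            )


def write_genotypes_vcf(gm: GenotypeMatrix, path: str):
    """Write hard-call dosages as GT, fractional dosages as DS."""
    hard = np.all(np.isin(gm.dosage[~np.isnan(gm.dosage)], [0.0, 1.0, 2.0]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if hard:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        else:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, snp in enumerate(gm.snps):
            fields = [
                snp.chrom, str(snp.pos), snp.snp_id, snp.ref_allele, snp.alt_allele,
                ".", "PASS", ".", "GT" if hard else "DS",
            ]
            for v in gm.dosage[:, j]:
                if np.isnan(v):
                    fields.append("./." if hard else ".")
                elif hard:
                    fields.append(gt_map[v])
                else:
                    fields.append(format(v, ".4f"))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Probe matrices

def read_probe_matrix(path: str, annotation_path: str, value_kind: str) -> ProbeMatrix:
    """Read a probes-x-samples TSV plus a probe annotation TSV.

    Matrix layout mirrors the dosage dialect: rows = probes, first column
    ``probe_id``, remaining columns = samples, ``NA`` for missing. The
    annotation TSV has columns ``probe_id chrom anchor_pos [gene_symbol]``.
    Every probe in the matrix must be annotated; beta matrices are
    validated to [0, 1].
    """
    mat = pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=["NA"])
    ann = pd.read_csv(annotation_path, sep="\t", comment="#", dtype={"chrom": str})
    ann = ann.set_index("probe_id")
    missing = [pid for pid in mat.index if pid not in ann.index]
    if missing:
        raise FormatError(f"unannotated probes: {', '.join(map(str, missing[:10]))}")
    probes = []
    for pid in mat.index:
        row = ann.loc[pid]
        gene = row.get("gene_symbol")
        probes.append(
            ProbeAnnotation(
                probe_id=str(pid),
                chrom=str(row["chrom"]),
                anchor_pos=int(row["anchor_pos"]),
                gene_symbol=None if gene is None or pd.isna(gene) else str(gene),
            )
        )
    return ProbeMatrix(
        samples=[str(c) for c in mat.columns],
        probes=probes,
        values=mat.to_numpy(dtype=float).T,
        value_kind=value_kind,
    )


def write_probe_matrix(pm: ProbeMatrix, path: str, annotation_path: str | None = None,
                       header_lines: list[str] | None = None):
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("\t".join(["probe_id"] + pm.samples) + "\n")
        for j, probe in enumerate(pm.probes):
            vals = [
                "NA" if np.isnan(v) else format(v, ".6f") for v in pm.values[:, j]
            ]
            fh.write("\t".join([probe.probe_id] + vals) + "\n")
    if annotation_path is not None:
        with open(annotation_path, "w") as fh:
            fh.write("probe_id\tchrom\tanchor_pos\tgene_symbol\n")
            for probe in pm.probes:
                fh.write(
                    f"{probe.probe_id}\t{probe.chrom}\t{probe.anchor_pos}\t"
                    f"{probe.gene_symbol or ''}\n"
                )


def read_covariates(path: str) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.map(str)
    return CovariateTable(df)


def write_covariates(ct: CovariateTable, path: str, header_lines: list[str] | None = None):
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df = ct.data.copy()
        df.index.name = "sample_id"
        df.to_csv(fh, sep="\t", float_format="%.6f")


# ---------------------------------------------------------------------------
# Tracks, GWAS lists, QTL tables

def read_track(path: str, name: str | None = None) -> IntervalTrack:
    """Read a BED3/BED4 file (0-based half-open) into an IntervalTrack."""
    intervals = []
    track_name = name
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("track"):
                for tok in line.split():
                    if tok.startswith("name="):
                        track_name = tok.split("=", 1)[1].strip('"')
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line needs >= 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            intervals.append((chrom, start, end))
    if track_name is None:
        track_name = os.path.splitext(os.path.basename(path))[0]
    return IntervalTrack(name=track_name, intervals=intervals)


def write_track(track: IntervalTrack, path: str):
    with open(path, "w") as fh:
        for chrom, start, end in track.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{track.name}\n")


def read_gwas_list(path: str) -> GwasSnpList:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    return GwasSnpList(df)


def write_gwas_list(gl: GwasSnpList, path: str, header_lines: list[str] | None = None):
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        gl.records.to_csv(fh, sep="\t", index=False)


def write_qtl_table(records: list[QtlRecord], path: str,
                    header_lines: list[str] | None = None):
    """Write QTL records as TSV, ordered by probe_id then ascending p."""
    ordered = sorted(records, key=lambda r: (r.probe_id, r.p_value, r.snp_id))
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("\t".join(QTL_TABLE_COLUMNS) + "\n")
        for r in ordered:
            fh.write(
                "\t".join(
                    [
                        r.snp_id,
                        r.probe_id,
                        str(r.distance_bp),
                        format(r.beta, ".6g"),
                        format(r.se, ".6g"),
                        format(r.t_stat, ".6g"),
                        format(r.p_value, ".6g"),
                        "1" if r.fdr_significant else "0",
                        format(r.r2_genotype, ".6g"),
                        format(r.r2_neuronal, ".6g"),
                        format(r.r2_age, ".6g"),
                        format(r.r2_gender, ".6g"),
                    ]
                )
                + "\n"
            )


def read_qtl_table(path: str) -> list[QtlRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for _, row in df.iterrows():
        records.append(
            QtlRecord(
                snp_id=str(row["snp_id"]),
                probe_id=str(row["probe_id"]),
                distance_bp=int(row["distance_bp"]),
                beta=float(row["beta"]),
                se=float(row["se"]),
                t_stat=float(row["t"]),
                p_value=float(row["p"]),
                fdr_significant=bool(row["fdr_significant"]),
                r2_genotype=float(row["r2_genotype"]),
                r2_neuronal=float(row["r2_neuronal"]),
                r2_age=float(row["r2_age"]),
                r2_gender=float(row["r2_gender"]),
            )
        )
    return records
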