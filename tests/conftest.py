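import numpy as np
import pytest

from cisqtl.io import GenotypeMatrix, ProbeAnnotation, ProbeMatrix, SnpAnnotation
from cisqtl.synth import (
    PlantedEffect,
    SimulationConfig,
    make_covariates,
    simulate_genotypes,
)


def make_genotypes(dosages, positions=None, chrom="chr1", sample_prefix="S"):
    """GenotypeMatrix from a dict snp_id -> dosage list (test helper)."""
    ids = list(dosages)
    arr = np.column_stack([np.asarray(dosages[i], dtype=float) for i in ids])
    n = arr.shape[0]
    positions = positions or {sid: 1000 * (k + 1) for k, sid in enumerate(ids)}
    snps = []
    for sid in ids:
        col = arr[:, ids.index(sid)]
        p = np.nanmean(col) / 2
        snps.append(
            SnpAnnotation(snp_id=sid, chrom=chrom, pos=positions[sid],
                          ref_allele="A", alt_allele="G", maf=min(p, 1 - p))
        )
    return GenotypeMatrix(
        samples=[f"{sample_prefix}{i}" for i in range(n)], snps=snps, dosage=arr
    )


def make_probe_matrix(values, positions, value_kind="beta", prefix="cg",
                      chrom="chr1", samples=None):
    values = np.asarray(values, dtype=float)
    probes = [
        ProbeAnnotation(probe_id=f"{prefix}{j}", chrom=chrom, anchor_pos=positions[j])
        for j in range(values.shape[1])
    ]
    return ProbeMatrix(
        samples=samples or [f"S{i}" for i in range(values.shape[0])],
        probes=probes, values=values, value_kind=value_kind,
    )


@pytest.fixture(scope="session")
def cohort110():
    """Default-sized cohort: 110 samples, 200 block-LD SNPs, covariates."""
    cfg = SimulationConfig(
        n_samples=110, n_snps=200, ld_block_size=10, seed=11,
        planted_meqtls=[PlantedEffect(25, 0, 0.5), PlantedEffect(105, 1, 0.24)],
    )
    gm = simulate_genotypes(cfg)
    cov = make_covariates(110, 11)
    return cfg, gm, cov
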