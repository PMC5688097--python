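# cisqtl

Cis-meQTL and cis-eQTL mapping for paired genotype / DNA-methylation /
gene-expression cohorts — the kind of analysis used to dissect how common
SNPs shape CpG methylation and transcript abundance in human brain tissue
(e.g. surgical hippocampus specimens), where cell-type composition, age,
sex and technical batches must all be adjusted before any association is
believable.

The package provides, as an importable library plus a thin `cisqtl` CLI:

- **QC and normalization** — SNP filters (call rate, MAF, exact
  Hardy–Weinberg test), the five-rule CpG-probe filter cascade and
  weak-expression filter, subset-wise quantile normalization, a
  `log2(x + 16)` expression transform, and control-probe PCA.
- **The cis-QTL scan** — for probe value *y*, SNP dosage *g* and covariate
  matrix *C* (known confounders: neuronal proportion, age, gender;
  genotype PCs; optional control-probe PCs; hidden-confounder PCs frozen
  from a first-pass residual PCA), fits the additive model

  *y* = α + β·*g* + *C*γ + ε

  for every SNP–probe pair within ±500 kb (inclusive), applies
  Benjamini–Hochberg step-up at 1% FDR jointly over all cis pairs of the
  scan, and reports per-term variance shares ΔR² (full model minus
  leave-one-term-out refit).
- **Methylation–expression correlation** on confounder residuals, with
  shared-genetic-driver detection (top meQTL and eQTL SNPs in LD,
  r² ≥ 0.4).
- **LD tools** — composite-LD r², greedy pruning (r² < 0.8 / 50 SNPs),
  PLINK-style clumping (r² < 0.25 / 250 kb keeping the most significant
  SNP), and MAF-matched control-set sampling.
- **Enrichment engines** — β-value-matched Fisher enrichment of QTL-CpGs
  across annotation tracks (seven-fold matched controls, exact two-sided
  p, Bonferroni q), and empirical LD-overlap enrichment of QTL-SNPs
  against GWAS or external QTL SNP sets
  (enrichment = observed overlap / null mean over MAF-matched control
  sets; empirical p = fraction of null sets reaching the observed count).
- **Prioritization** — CADD-score thresholding with best-SNP-per-probe
  selection, CpG creation/abolition calls from allele context, TFBS joins
  and GWAS-catalog matching.
- **A synthetic-cohort generator** reproducing the statistical structure
  the analysis assumes (block-LD dosages, bimodal β-values, planted cis
  effects of 10–85% variance, covariate effects), so the full stack is
  testable without patient data.

## Worked example

`examples/01_simulate_and_scan.py` simulates 110 samples × 200 SNPs with
two planted meQTLs (50% and 35% of probe variance) and scans all cis
pairs:

```
tested 12000 cis pairs
significant pairs at 1% FDR: 11 (p threshold 5.63e-06)
CpGs with >=1 significant SNP: 3
  snp00025 -> cg00000: beta=+0.101 p=1.12e-13 genotype R2=0.58
  snp00026 -> cg00000: beta=+0.101 p=5.25e-12 genotype R2=0.56
  snp00025 -> cg00007: beta=-0.074 p=1.16e-11 genotype R2=0.05
```

The planted SNP (snp00025) and its LD proxy (snp00026) top the list; the
genotype-R² column recovers the planted variance fraction (0.58 vs the
planted 0.50, within sampling error at n = 110), and β is the per-allele
methylation change on the β-value scale. The remaining examples cover
the methylation–expression correlation with a shared genetic driver,
annotation enrichment (planted odds 1.8 recovered as OR ≈ 1.7), empirical
LD-overlap enrichment (designed three-fold overlap recovered as ≈ 3.2)
and the deterministic end-to-end pipeline.

## Command line

```bash
cisqtl run-all --out run/ --seed 7          # simulate -> qc -> scans -> enrichments
cisqtl scan-meqtl --out run/ --fdr 0.01 --window-kb 500
cisqtl validate --config config.yaml        # echo fully-defaulted parameters
```

All outputs are TSV with a `#`-prefixed provenance header; `run-all`
writes a `manifest.json` of SHA-256 digests that is byte-identical for
identical (config, seed).

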