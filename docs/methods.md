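# Methods

## The model

Each cis scan fits, for probe value *y* (CpG β-value or log2 expression)
and SNP dosage *g* ∈ [0, 2],

  y = α + β g + C γ + ε,

by ordinary least squares, where the covariate matrix *C* stacks the known
confounders (neuronal cell proportion, age at sampling, gender), the
first genotype principal components (population stratification), optional
control-probe PCs (array technical bias, methylation only), and
hidden-confounder PCs. Hidden PCs are computed once from the residuals of
the probe matrix over the known confounders and then frozen as fixed
columns — a two-pass design: the scan never re-estimates them per SNP.
The dosage t-statistic has n − k degrees of freedom (k = number of model
columns including the intercept); significance is controlled by
Benjamini–Hochberg step-up at 1% FDR applied **jointly over all cis pairs
of a scan**, which yields a single data-dependent p-threshold per scan
(reported in the scan summary). A pair is cis when SNP and probe anchor
share a chromosome and are at most 500 kb apart; the boundary is
inclusive at exactly 500,000 bp and this convention is used everywhere
(probe QC rule (v), pair enumeration, correlation windows). The distance
anchor is the CpG coordinate for methylation and the transcript 5′-TSS
for expression probes; the correlation analysis windows on the expression
probe.

Internally the scan uses the Frisch–Waugh–Lovell decomposition:
probe values and dosages are residualized on the covariate design once
(QR-based projection), and per-pair β, SE, t and p are recovered from
residual cross-products. This is algebraically identical to refitting the
full model per pair (the test suite asserts equality with an explicit
normal-equations oracle to 1e-8) but runs as a handful of matrix
products.

Per-record variance shares are leave-one-term-out ΔR²: share(T) =
R²(full) − R²(refit without T), computed for the genotype and for each
known confounder, clipped at zero when non-orthogonality makes the refit
difference negative. With no covariates the genotype share reduces to
t²/(t² + df), which the tests assert. The published per-covariate
variance figures do not name a decomposition; leave-one-term-out refit is
this package's documented choice.

## Statistical primitives

- **Hardy–Weinberg**: exact conditional test — the two-sided p sums the
  probabilities of all heterozygote counts (given the allele counts) that
  are no more probable than the observed one. Monomorphic markers return
  p = 1 by convention. Chosen over the chi-square approximation for
  robustness at small counts.
- **Fisher 2×2**: OR by cross-product; exact two-sided p by the
  point-probability rule over the hypergeometric support (pmf cached per
  margin set); 95% CI by the log-OR normal approximation; a zero cell
  triggers a 0.5 continuity correction for the OR/CI and is flagged.
  An exhaustive sweep against an integer binomial-coefficient oracle over
  every table with total ≤ 60 agrees to 1e-15.
- **BH-FDR**: direct step-up; returns flags plus the largest rejected p
  (0 when nothing is rejected). Cross-checked against
  statsmodels `multipletests`.
- **LD r²**: squared Pearson correlation of dosage vectors (composite
  LD), matching PLINK's behavior on unphased genotypes; missing dosages
  mean-imputed at computation time, never in the stored matrix.
- **Clumping**: iteratively index the smallest-p unassigned SNP (ties →
  smaller position) and absorb unassigned SNPs with r² ≥ 0.25 within the
  window. Index sets are asserted mutually quasi-independent and the
  clump conserves the input set on every synthetic run.
- **Quantile normalization** operates within probe subsets (a single
  subset = whole matrix): each sample's values are replaced by the mean
  empirical quantile function evaluated at their fractional rank, so ties
  receive interpolated reference values and the procedure is idempotent
  to 1e-10 on complete matrices; missing values are excluded from ranking
  and restored.

## Enrichment engines

**Annotation enrichment** matches each target CpG with `match_ratio`
(default 7) control CpGs drawn without replacement from the same
median-β decile bin (bins [0, 0.1) … [0.9, 1]); the control set is
sampled once per run and reused for all tracks; q-values are Bonferroni
over the tracks actually tested. Median is the default matching
statistic (a mean option exists). CpG-in-track membership treats the CpG
as its two-base dinucleotide footprint, so an interval touching either
base counts.

**LD-overlap enrichment** clumps the target, reference and control-pool
SNP sets (r² < 0.25 within 250 kb), optionally masks a configured region
(default follows the source convention `chr6:2,500,000–3,500,000`,
configurable because that printed interval is inconsistent with the
canonical MHC locus at ~chr6:28–34 Mb), counts target SNPs with at least
one reference SNP at r² ≥ 0.25 within the overlap window (250 kb for
GWAS comparisons, 1 Mb for eQTL-vs-meQTL), and draws `n_sets`
MAF-matched control sets from the clumped non-QTL pool (SNPs with
FDR > 10% in the scan). Enrichment = observed / null mean; empirical
p = k/n_sets with k the number of null sets reaching the observed count,
reported as an upper bound 1/n_sets when k = 0 (a (k+1)/(n+1) estimator
is available via flag). The default is 10,000 null sets — the estimator
is unchanged from larger runs, only its Monte-Carlo error — with the
count configurable upward. Pool overlap flags are precomputed once, so
each null set costs a binned draw plus a sum. MAF bins default to 0.02
width for genome-scale pools; the pipeline's desk-scale default is 0.1
because small clumped pools leave 0.02-bins empty.

## The synthetic cohort

The generator reproduces the structure the analysis assumes, not the
biology of any particular tissue:

- **Genotypes**: blocks of SNPs share a block allele frequency (uniform
  on the MAF range, default [0.05, 0.5]); each haplotype allele copies
  the previous SNP's allele with probability √r²_target and is redrawn
  otherwise, so adjacent-pair r² hits the target (default 0.8) and LD
  decays geometrically within the block; blocks are independent; SNPs sit
  at fixed 2 kb spacing on one synthetic chromosome, which makes
  cis-window edge cases enumerable. Columns drifting outside the MAF
  range are redrawn; targets above r² = 0.98 are rejected as unreachable.
- **Methylation**: each CpG has a logit-scale liability
  μ_class + 0.5·(genotype + covariate + noise), the bracketed term
  standardized to unit variance with component variances equal to the
  requested fractions, mapped through the inverse logit. Class means
  (−3, 0, +3) with default weights (0.45, 0.10, 0.45) give the bimodal
  background (modes near β = 0.05 and 0.95). Planted QTL CpGs are placed
  in the intermediate class, where the logistic map is near-linear: the
  realized β-scale R² of a planted effect then tracks the liability-scale
  fraction to within ~0.01 across the 0.11–0.85 range (measured by the
  parameter-recovery tests, not assumed). No published noise model for
  β-values exists; this logistic-liability construction is a documented
  stand-in.
- **Expression**: same machinery on a Gaussian log2 scale (baseline
  uniform on [6, 12]), no logistic transform. Planting the same SNP as a
  meQTL and an eQTL creates genuinely correlated CpG/transcript pairs
  for the shared-driver analysis.
- **Covariates**: gender ~ Bernoulli(0.5), age uniform on [1, 67] years,
  neuronal proportion 0.2 + 0.6·Beta(2, 2); default covariate variance
  fractions (neuronal 5%, age 3%, gender 1%) mirror the reported modest
  covariate contributions.
- **Tracks**: a CpG is covered with probability q (QTL) or p = 0.15
  (background) with odds(q)/odds(p) equal to the requested enrichment
  odds; covered CpGs contribute ±100 bp intervals.
- **GWAS lists**: a chosen fraction of hits is drawn from LD blocks
  containing QTL-SNPs, the rest from other blocks, with p-values below
  5×10⁻⁸.

What the generator does **not** model: realistic recombination maps,
population structure, array background noise, probe cross-hybridization
artifacts. Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under the assumed model, not
performance on real arrays.

## Problem sizes and numerical choices

The default test and acceptance runs use desk-scale cohorts chosen to
make the relevant estimators well-conditioned: 110 samples throughout
(the cohort size the design targets); 200–750 SNPs in blocks of 5–10;
null-FDR calibration over 200 replicate cohorts of 500 SNPs × 200 CpGs;
parameter recovery at n = 2000 with 50 replicates; annotation enrichment
at 5,000 target CpGs against a 55,000-CpG pool; LD-overlap enrichment
with 10,000 null sets over 150 five-SNP blocks. The planted GWAS-overlap
scenario is sized so its design value (~3.3×: target-side hit rate 27/30
vs pool rate 33/120) sits well inside the recovery band with small
Monte-Carlo error.

Degenerate inputs are handled explicitly: monomorphic dosages are
skipped with a logged count (scan) or raise (single fits, LD);
zero-variance residual pairs are skipped in the correlation; desk-scale
annotation pools that cannot support the full match ratio shrink it (and
drop unsupportable β bins) with a note in the output header; degenerate
2×2 margins at desk scale yield an empty enrichment table rather than an
error. Probe matrices with missing values are mean-imputed per probe at
fit time only.

One desk-scale caveat the examples expose: with only a few hundred SNPs,
genotype PCs (and hidden PCs over few probes) can partially align with
individual LD blocks and act as suppressor covariates, occasionally
promoting a background probe past the joint-BH threshold in planted
scenarios. Null calibration is unaffected (the 200-replicate null run
declares ~0.01% of probes), and at realistic panel sizes PCs reflect
genome-wide structure rather than single blocks.

## Pipeline and reproducibility

Stages (`simulate → qc → scan-meqtl → scan-eqtl → correlate →
enrich-annotation → enrich-ld`) communicate through TSV files, so any
downstream stage can be rerun from cached inputs and reproduces its
full-pipeline output. Per-stage seeds derive from the master seed via
`SeedSequence(master, spawn_key=(counter,))` with a fixed counter per
stage name, so adding a stage never shifts another stage's random
stream. Outputs carry version/seed/parameter provenance headers and no
timestamps; the manifest of SHA-256 digests is a pure function of
(inputs, config, seed). Genotypes support hard calls and fractional
dosages; hard calls are the default analysis input, with HWE computed on
(rounded) hard calls.

## Known limitations

- The scan is cis-only by design; no trans associations, no dominance or
  interaction terms.
- ISVA-style surrogate-variable adjustment is not implemented; hidden
  confounders are handled by residual PCA only.
- The β-value noise model is a logistic-liability stand-in (see above).
- The empirical-enrichment p-value resolution is 1/n_sets; runs that
  need p below 10⁻⁴ must raise `n_sets`.
- CADD scores, TFBS predictions and GWAS catalogs are consumed as static
  tables; nothing is recomputed or fetched.
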