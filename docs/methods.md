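# Methods

This note documents the models, defaults and numerical choices behind
`pgx-triangulate`, and what the synthetic-cohort experiments do and do not
demonstrate.

## Dose-response model and the AUC phenotype

Viability fractions (normalized to the untreated control) are modelled per
cell line with the four-parameter log-logistic
`f(x) = c + (d − c)/(1 + (x/e)^b)`, where `b` is the slope, `c` the lower
asymptote (residual viability at saturating dose), `d` the upper asymptote
and `e` the half-maximal dose in nmol/L. The parameterization takes the
dose-0 control point directly (`f(0) = d` by continuity) without
log-transforming dose. The phenotype is the integral of the *fitted* curve
on [0, 320] nmol/L, computed with adaptive quadrature at relative tolerance
1e-9; integrating the fit rather than the raw means smooths replicate noise
and is the choice this package commits to.

Fitting is bounded least squares (`scipy.optimize.least_squares`) with
bounds `c ∈ [−0.1, 1.1]`, `d ∈ [0.5, 1.5]`, `b ∈ (0, 10]`,
`e ∈ (0, 10 × max dose]` — wide enough for real curves, tight enough to keep
a 4-parameter model identifiable on a 9-point grid. Initialisation: `d` =
mean viability at dose 0, `c` = mean at the top dose, `e` = the dose whose
mean is nearest (c+d)/2, `b` = 1; three perturbed restarts run only if the
first attempt fails. Optimizer failure never raises: the sample is flagged
`converged=False` and receives a trapezoid-of-dose-means fallback AUC, so
no cell line is silently dropped. Fits require ≥ 5 distinct doses including
dose 0. On noise-free curves across the tested (b, e) grid, parameters are
recovered to ~1e-13 relative error and AUC matches quadrature of the true
curve to well under 0.1%.

## SNP quality control

Filters run sequentially — call rate, then MAF, then HWE — with strict `<`
removal (a SNP at exactly 95% call rate or 5% MAF is retained). Each SNP is
tagged with the *first* filter it fails, and the ledger invariant
`input = retained + Σ removed` is asserted on every run. The retained set is
order-independent (the filters are per-SNP predicates); only the per-filter
attribution changes with order, and both facts are tested. The HWE test is
the 1-df goodness-of-fit chi-square against expected genotype counts at the
estimated allele frequency, computed on the pooled sample by default (a
per-race option exists); the removal threshold defaults to p < 1e-6, a
conventional array-QC value consistent with HWE removing only a tiny
fraction of markers. MAF and HWE denominators exclude missing genotypes
allele-wise. Imputed markers (those carrying an imputation-quality INFO
value) face their own filters — MAF < 0.01 or dosage R² < 0.3 — and are
exempt from the genotyped-panel 5% rule. Cross-platform deduplication keys
on shared rsID, else (chrom, pos); the first-listed platform wins and
genotype conflicts at duplicated sites are counted and logged.

## Covariate adjustment

The AUC phenotype is Van der Waerden transformed: rank r of n maps to the
standard-normal quantile at r/(n+1), average ranks for ties. This makes the
phenotype distribution-free before regression; expression (already log2)
and genotypes (rare-allele counts) are not rank-transformed.

Population stratification is addressed with within-race principal
components: genotypes are LD-thinned (greedy windowed pruning, window 50
SNPs, step 5, r² > 0.2 pruned, the lower-MAF member dropped — conventional
stratification-PCA practice), then per race each SNP is standardized over
that race's samples and the top 5 left singular vectors give the scores.
Scores are *race-blocked*: a sample carries its own race's five columns and
exact zeros elsewhere, which realises "PCA within each race" inside one
pooled design of intercept + sex + race indicators + 15 PC columns. The
design is checked for full rank and offending columns are named.

Each variable is replaced by its OLS residuals on that design, standardized
to mean 0, SD 1 (population convention, so a partial correlation is a dot
product over n). Zero-residual-variance rows are flagged and excluded with
a logged reason. SNPs with missing genotypes are residualized on their
observed subsample; the association uses pairwise-complete samples with the
residual degrees of freedom reduced to `n_complete − 2 − k`. Expression and
AUC are residualized once on the full design and recentred over each
subset, not re-residualized per missingness pattern — an approximation that
is exact without missingness and, at the 2% default missing rate, leaves
the null calibration measurably nominal (see below).

## Association tests and FDR

The association statistic between two adjusted variables is the Pearson
correlation of their residual vectors — the partial correlation given the
design — tested with `F = r²·df/(1−r²)` on (1, df) degrees of freedom,
df = n − 2 − k with k the number of non-intercept design columns. This is
the squared-t convention for one regression coefficient; charging the
covariate count in df is what makes the null calibration exact at modest n.
Underflowed p-values are reported as the smallest positive double so
−log10 p stays finite.

Storey q-values use a fixed λ = 0.5 (no spline smoothing):
π̂0 = #{p > λ}/(m(1−λ)) clamped to [1/m, 1], with the usual step-up minima,
capped at 1; with π0 fixed at 1 the output is exactly Benjamini–Hochberg
(tested to 1e-14). q-values are computed within each analysis family
(snp~auc, expr~auc, snp~expr) separately, since each family has its own
null scale.

Measured calibration, recomputed by `scripts/acceptance.py`: on a 10,000-SNP
null cohort the rejection rate at α = 0.05 is ≈ 0.050–0.052; the realized
FDR of q ≤ 0.05 on a 90/10 null/alternate mixture over 200 replicates is
≈ 0.05 within Monte-Carlo error.

## Triangle integration and peak regions

Default thresholds: SNP~AUC p < 1e-4, SNP~expression p < 1e-4,
expression~AUC p < 1e-3 (all configurable); a triangle must pass all three,
and unique SNPs are counted after deduplication across probes. "Within
50 kb" peak regions are implemented as single-linkage chaining: qualifying
SNPs (p < 1e-4) on one chromosome join a chain while consecutive members
are ≤ 50,000 bp apart (boundary inclusive); chains need ≥ 2 members.
Chaining is verified against an O(n²) union-find oracle. Regions are
written as BED (0-based half-open, converted from internal 1-based
inclusive coordinates; the conversion is unit-tested). The low-expression
candidate filter compares the *median* across samples of linear-scale
expression against 50 — the median is robust to a few high-expressing
lines, and the summary statistic had to be fixed somewhere. The cis window
defaults to 1 Mb from the gene span; probes without a map entry are flagged
`unknown`, never silently cis or trans.

## Synthetic cohort: what it emulates, and what it does not

The generator reproduces the study design the pipeline targets: 278 samples
in three ancestry groups (93/91/94), a common-variant panel, log2
array-scale expression and triplicate viability on the 9-dose grid.
Choices, each fixed once:

- **Allele frequencies.** Ancestral rare-allele frequency uniform on
  [0.05, 0.5]; per-race frequencies are Balding–Nichols Beta draws at
  Fst = 0.05, a typical continental-scale divergence. Genotypes are two
  Hardy–Weinberg Bernoulli alleles; the drift parameter is recoverable from
  the stored race frequencies by a moment estimator (tested).
- **Expression.** Baselines uniform on log2 [3.5, 11], so a realistic
  minority of probes fall under the linear-scale 50 boundary
  (2^5.64 ≈ 49.9); Gaussian noise SD 0.5 log2 units, typical of array
  probe-level variability. Planted eQTLs act additively per rare allele
  through the true (pre-missingness) genotypes.
- **AUC.** Latent AUC = 180 + planted effects + N(0, 40), clipped 1 unit
  inside the attainable range (16, 320) of the inversion curve — the
  attainable range is fixed by the inversion shape (b = 1.5, c = 0.05,
  d = 1.0), and clipping mimics assay saturation. No published AUC moments
  exist for this assay, so location and spread are the package's choice of
  a plausibly wide sensitivity range.
- **Viability rendering.** Each sample's AUC is inverted to a half-maximal
  dose `e` by monotone root finding (Brent on log e; the curve integral is
  evaluated with 200-point Gauss–Legendre, accurate far beyond the 0.5%
  round-trip tolerance). One free parameter keeps the AUC → curve map
  invertible and the shapes realistic. Gaussian noise SD 0.03 viability
  units, clipped at 0 but not above 1 (plate readings can exceed control).
  AUC exactly at the upper bound maps to the flat-curve limit e = ∞.
- **Missingness** is completely at random at 2%.
- **Randomness** flows from one master seed through named substreams
  (genotype / expression / auc / viability / sex), so identical specs
  produce byte-identical files and stages can be regenerated independently.

Not modelled: linkage disequilibrium beyond race-level drift (no
haplotypes), batch or plate effects, EBV-transformation artefacts, and any
genotype–environment structure. Passing the planted-chain experiments
therefore shows the *pipeline machinery* is correct and calibrated — not
that real-data hits at these thresholds would validate; on real cohorts LD,
batch structure and winner's curse all matter and are out of scope here.

### Planted-chain experiment design

Recovery experiments plant one strong chain — SNP → probe (+1 log2
unit/allele) → AUC (+40 per log2 unit) — at a deliberately *common* SNP
(ancestral frequency ≥ 0.2, so the causal marker is not itself at risk from
the 5% MAF filter) and a well-expressed probe (log2 baseline in [6.5, 10],
clearing the linear ≥ 50 candidate filter). This mirrors how one designs a
positive control; the pick uses a two-pass construction that is exactly
reproducible because the genotype and expression substreams do not depend
on the planted-effect registry. Experiments run at 1,000 SNPs × 250 probes
× 278 samples, 20 seeds — sizes chosen so the full suite stays interactive
on a single CPU while the all-pairs snp~expr scan still covers ~240,000
tests per run.

## Known limitations

- The pairwise-complete treatment of genotype missingness recentres but
  does not re-residualize the partner variable on each subset; exactness
  holds only without missingness (calibration at the default 2% rate is
  nominal, as measured).
- The log-logistic fit can return `c > d` on pathological increasing
  dose-response data; such data indicate the assay, not the fit, failed.
- Peak-region and cis/trans geometry on synthetic cohorts uses the
  generator's synthetic marker map (fixed 5 kb SNP spacing, synthetic gene
  spans); real annotation must be supplied by the user.
- `run_pipeline` executes stages within one process and one output
  directory; it does not resume partially completed runs (failed stages
  leave a `.partial` marker).
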