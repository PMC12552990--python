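# Methods

## Problem and model

`repeatmeth` detects carriers of the pathogenic GGGGCC hexanucleotide repeat
expansion in the *C9orf72* promoter region from whole-blood DNA methylation
measured on Illumina EPIC-style arrays. The expansion is the most common
genetic cause of frontotemporal dementia and ALS, and carriers show marked
hypermethylation of CpGs in and around the gene. The package implements the
analysis chain around that signal; all statistics operate on M-values
(log2 methylated/unmethylated odds), the variance-stabilised scale preferred
for linear modelling of array methylation.

### Per-probe differential methylation

For each CpG probe *g*, the M-value is modelled by ordinary least squares:

    M_g = b0 + b1·carrier + b2·age + b3·sex + Σ b·cell_fractions
          + b·smoking_score + batch dummies + e,   e ~ N(0, σ_g²)

One of the six leukocyte fractions (neutrophils, the dominant one) is
dropped because the fractions sum to one; batch enters dummy-coded with the
first level as reference. The carrier coefficient b1 is the reported effect
("logFC" on the M scale). The design matrix is shared across probes, so the
whole scan is a single QR decomposition plus matrix products.

Residual variances are moderated by empirical Bayes before forming
t-statistics. A scaled inverse-chi-square prior (d0, s0²) is fitted to the
observed sample variances by matching the mean and variance of log s²
(inverting the trigamma function for d0); each probe then uses the posterior
variance s̃² = (d0·s0² + d·s²)/(d0 + d) and the moderated t has d0 + d
degrees of freedom. When the observed spread of log-variances does not
exceed the chi-square sampling variability, d0 is infinite; in that
degenerate branch we use the arithmetic mean of the sample variances as the
shared variance (the exactly unbiased pooled estimator), a deliberate
departure from the bias-corrected geometric mean some implementations use
there — in the exactly-homogeneous case this makes the moderated fit
coincide with the pooled-variance fit. In the regular branch the fit matches
the R/Bioconductor reference implementation to machine precision (verified
in the test suite on a 200-probe fixture).

Probes with zero M-value variance or zero residual variance are flagged and
excluded from ranking, moderation and the permutation null rather than
assigned p = 1.

### Multiple testing and inflation diagnostics

Adjusted p-values use Benjamini–Hochberg (delegated to
`statsmodels.stats.multitest`; the procedure name is recorded in result
metadata). The genomic inflation factor is computed from two-sided p-values
mapped to 1-df chi-square quantiles, λ_gc = median(χ²_obs) / 0.4549…,
reported at three decimals. Values near 1 on the null background probes
indicate the covariate adjustment leaves no systematic confounding.

### Permutation significance threshold

With 27 carriers among 277 samples, fixed genome-wide thresholds can be
poorly calibrated, so the significance cut is data-derived: carrier labels
are shuffled without replacement across samples (preserving the 27/250
margin; covariates stay attached to their samples so the null retains the
covariate and batch structure), the full moderated scan is re-run per
shuffle (default B = 100), and the threshold is the smallest carrier
p-value seen in any shuffle. Probes are called significant when p is
strictly below the threshold. A shuffle that reproduces the original
labelling is a valid draw and is kept (counted); a shuffle yielding a
rank-deficient design is re-drawn and the re-draw count reported.

### Locus classifier

Prediction is restricted to the locus probes (gene body ± 1 kb; 23 probes on
EPICv2, shrinking to 12/5/2 on EPICv1/450K/27K). Features are standardised
by training mean/SD; an L1-penalised logistic regression is fitted with the
penalty chosen to minimise mean 10-fold cross-validated binomial deviance
over a geometric path from λ_max (the smallest penalty that zeroes all
coefficients) down four decades — i.e. the deviance-minimising λ, not the
1-SE rule. CV folds are stratified by carrier status so each fold contains
carriers; the final model is refit on the whole training set. The solver
tolerance is set tight (1e-8) so fitted probabilities are reproducible to
~1e-6 under feature duplication or affine rescaling. Classification uses
probability > 0.5.

Train/test splits are stratified 70/30 by default: per class the training
count is round(0.7 · n_class), so a 277-sample cohort yields 194 training
samples with 19 carriers. Plain random splitting is available behind a flag,
in which case a carrier-free test split reports an undefined (NaN)
false-negative rate. Repeated evaluation re-draws the split and refits the
model n times (default 100) with per-iteration seed = root_seed + i, and
summarises accuracy, type I (FP among true non-carriers) and type II (FN
among true carriers). Platform comparison runs the same evaluation on each
platform's probe subset with shared split seeds (paired design; independent
seeds behind a flag) and compares per-iteration metric distributions with a
two-sided Welch t-test (rank-sum available by flag); the test name is
recorded in the output.

## Synthetic cohorts

No individual-level methylation data ship with the package; every analysis
is exercised on synthetic cohorts with known ground truth. The generator
emulates:

- **Cohort design** — 277 samples with 27 carriers by default; optional
  call-rate-failing samples (forced missingness above the 5% filter) and
  samples without a repeat assay (carrier label `unknown`), so the
  440 → 434 → 277 filtering arithmetic of a realistic intake is testable.
- **Probe universe** — the packaged 23-probe locus manifest plus null
  background probes (default 20,000) spread over the autosomes.
- **Baselines** — mean beta per island context (island 0.15, shore 0.35,
  shelf 0.55, open sea 0.75, reflecting canonical island hypomethylation)
  converted to M, plus per-probe jitter (SD 0.5 M).
- **Carrier effect** — additive M-shifts at chosen locus probes. The default
  profile implants the eight top locus probes with shifts decreasing
  linearly +4.0 → +1.5 M units. Published per-probe fold-change figures are
  implausibly large read literally as M differences, so the defaults were
  chosen once as strong-but-realistic shifts detectable at this sample size;
  they are configuration, not estimates.
- **Nuisance structure** — covariate slopes (age, sex, smoking score,
  neutrophil fraction) applied to a random 10% of probes; per-(probe, batch)
  offsets (SD 0.2 M) on 20% of probes across 4 batches; covariates sampled as
  age ~ N(63, 8) truncated to [30, 95], sex ~ Bernoulli(0.4), leukocyte
  fractions ~ Dirichlet (neutrophil-dominant means, concentration 60),
  smoking score ~ N(0, 1).
- **Noise heterogeneity** — per-probe residual SDs are lognormal (median
  0.4 M, log-SD 0.4), giving the variance spread that empirical-Bayes
  moderation exists to shrink.

All randomness flows from one root `SeedSequence` split into named child
streams (labels, covariates, baselines, effects, noise, missingness), so
runs are bit-reproducible given the seed and the independent validation
cohort is generated from a distinct stream of the same seed.

What the generator does **not** emulate: raw fluorescence intensities,
type I/II probe chemistry, normalisation artefacts, probe cross-reactivity
beyond manifest flags, spatial correlation between neighbouring CpGs, or
repeat-length dosage effects. Passing tests therefore demonstrate that the
statistical machinery is correct and well calibrated under the assumed
generative model — not that real cohorts will achieve the same error rates.

## Numerical choices and degenerate inputs

- Beta-values are clipped to [1e-6, 1 − 1e-6] before the log-odds
  transform, so boundary betas map to large finite M-values.
- Probes with any missing value among retained samples are dropped before
  modelling (per-probe OLS needs complete columns; imputation is out of
  scope). Sample-level filtering (missing fraction > threshold) runs first.
- Rank-deficient designs raise, naming the collinear columns; designs need
  at least two more samples than columns.
- λ_gc of a degenerate all-ones p-vector is 0 with a warning.
- PCA component signs are fixed by making the loading of the
  alphabetically-first probe non-negative.
- Trigamma inversion uses Newton iteration from x = 0.5 + 1/y, converging in
  a handful of steps for all practical inputs.

## Problem sizes used in the shipped checks

The reference conditions (277 samples, 27 carriers, 20,000 background
probes, B = 100 permutations, 100 evaluation iterations) run in a few
minutes on one CPU and are used as-is for the end-to-end checks. Unit and
property tests use smaller instances chosen for the property being tested:
toy fits of ≤ 10 samples against an independent least-squares oracle,
1,000-probe variance-shrinkage simulations, 20–25-iteration platform
comparisons, and a locus-only (23-probe) cohort where background probes are
irrelevant.

## Known limitations

- The permutation threshold is a global min-p cut; per-probe step-down
  adjusted p-values (Westfall–Young) are intentionally out of scope.
- Covariates are taken as given (or simulated); reference-based cell
  deconvolution and smoking-score derivation from the array are upstream of
  this package, as are IDAT parsing and normalisation.
- With only 27 carriers, unstratified splits can produce carrier-free test
  sets; stratification is the default precisely to keep error rates defined.
- The island annotations of locus probes without a published context are
  inferred from position relative to the locus CpG island interval
  (chr9:27,573,600–27,574,050 with 2-kb shore and 4-kb shelf bands chosen to
  be consistent with every published annotation at this locus).
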