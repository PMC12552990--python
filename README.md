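# repeatmeth

Detection of pathogenic *C9orf72* repeat-expansion carriers from blood DNA
methylation.

The GGGGCC hexanucleotide repeat expansion in the *C9orf72* promoter is the
most common genetic cause of frontotemporal dementia and ALS. Carriers show
strong local hypermethylation of CpGs in and around the gene, measurable on
standard Illumina EPIC-style arrays. `repeatmeth` is for epigenetics groups
who want to (a) scan an array cohort for that signature with proper
covariate adjustment and calibrated significance, and (b) call likely
carriers in any cohort with available methylation data — for example large
psychiatric or population cohorts where nobody has run a repeat assay.

## What it computes

Working on M-values (M = log2 β/(1−β)), the package provides:

- **Per-probe differential methylation** — for each CpG *g*,
  `M_g ~ carrier + age + sex + cell fractions + smoking + batch` by least
  squares, with empirical-Bayes variance moderation: a scaled
  inverse-chi-square prior (d0, s0²) is fitted to the residual variances
  and each probe uses the posterior variance
  s̃²_g = (d0·s0² + d·s²_g)/(d0 + d), giving moderated t-statistics on
  d0 + d degrees of freedom. Benjamini–Hochberg adjusted p-values and the
  genomic inflation factor λ_gc (median observed 1-df chi-square over its
  null median) come with the fit.
- **A permutation significance threshold** — carrier labels are shuffled B
  times (default 100), the full moderated scan re-run per shuffle, and the
  smallest null p-value anywhere becomes the genome-wide cut: nothing
  weaker than the most extreme label noise is called.
- **A locus-restricted carrier classifier** — L1-penalised logistic
  regression on the 23 CpG probes within the gene ± 1 kb, penalty chosen by
  10-fold cross-validated binomial deviance, evaluated over repeated
  stratified 70/30 splits (accuracy, type I = FP among non-carriers,
  type II = FN among carriers), including the degradation when restricted
  to the probes surviving on older platforms (EPICv1: 12, 450K: 5, 27K: 2).
- **Frozen-model application** — a trained model serialises to plain text
  and can be applied to an independent cohort, returning per-sample carrier
  probabilities, the called carriers and the implied prevalence.

No subject-level data ship with the package; a synthetic-cohort generator
(`repeatmeth.simulate`) reproduces the statistical structure of such a
study — 277 samples with 27 carriers, implanted locus hypermethylation,
covariate/batch confounding, heterogeneous probe noise — so the whole chain
is testable and demonstrable offline.

## Worked example

```python
import repeatmeth as rm

cfg = rm.implant_carrier_profile(rm.SimulationConfig(n_background_probes=2000, seed=1))
ds, ann, truth = rm.generate_cohort(cfg)

res = rm.DifferentialMethylationModel(ds).fit()
print(res.summary(top=8))
```

```
Differential methylation analysis
=================================================
probes tested:        2023
residual df:          264
variance moderation:  empirical Bayes
prior df (d0):        4.04
prior variance s0^2:  0.12
lambda_gc:            0.964

            coef      se     t          p      adj_p
cg13533410 4.035 0.07093 56.88 1.247e-151 2.523e-148
cg03854581 2.167 0.04142 52.31 1.108e-142 1.121e-139
cg01589155 3.262 0.08226 39.66  3.79e-114 2.556e-111
...
```

The eight implanted locus probes top the ranking (`coef` is the carrier
effect in M units — all positive, i.e. hypermethylated in carriers), and
λ_gc ≈ 1 on the null background shows the covariate adjustment leaves no
systematic inflation. Continuing with the permutation threshold and the
classifier:

```python
perm = rm.permutation_threshold(ds, n_permutations=20, seed=1)
print(perm.summary())
hits = res.call_significant(perm.significance_config())

probes = rm.select_locus_probes(ann, "epicv2")
ev = rm.repeated_evaluation(ds, probes, n_iterations=10, root_seed=1)
print(ev.summary())
```

```
Permutation threshold (20 label shuffles, seed 1)
  min p per shuffle: min 2.85e-05, median 0.000242, max 0.000857
  threshold: p < 2.85e-05
  identity shuffles: 0; re-drawn: 0
8 probes pass the permutation threshold; all {'hyper'}
mean accuracy 1.000, type I 0.0000, type II 0.000
```

Exactly the eight implanted probes survive the permutation cut, and the
locus classifier separates carriers essentially perfectly under these
strong-effect conditions.

The same stages are available from the shell (`repeatmeth simulate / dma /
train / predict / evaluate / apply`), or as one configured run:

```
repeatmeth run --config cfg.yaml
```

which writes result tables plus a `manifest.json` recording versions,
seeds, parameters and input hashes; identical config + seed reproduces
byte-identical outputs.

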