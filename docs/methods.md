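# Methods

This note documents the statistical models implemented in `hmcseal`,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that
matter for reproducing results.

## 1. Counting model

Aligned fragments (BED, 0-based half-open; GFF converted at the
boundary) are counted over feature catalogs. A fragment increments
every feature it overlaps by ≥ 1 bp, independently within each
category; fragments with MAPQ < 10 or off the configured autosomes are
excluded, and strand is ignored. Within a category, a fragment spanning
two overlapping features increments both — categories are analyzed
independently, so no attempt is made to resolve multi-overlap
ambiguity. Features with mean count ≤ 10 across samples are removed
before modeling (strict inequality).

Promoters are 3 kb upstream of the strand-aware 5′ gene end ("upstream"
is read strand-aware; an unstranded gene is an error, not a guess). CpG
islands are extended ± 1 kb; peak sets are collapsed transitively when
closer than 150 bp. Metaprofiles length-normalize feature bodies into
`n_bins` bins plus fixed-width flank bins and, above 20 000 features,
sample from the interquartile length range (seeded).

## 2. Spike-in QC

Libraries carry a 5hmC-bearing and a modification-free probe at fixed
mass (default 2.6 fg) against 1–20 ng cfDNA input. The enrichment fold
is the ratio of the experimental (pull-down) group's 5hmC:no5hmC read
ratio to the control (no pull-down) group's; group ratios are means of
per-library ratios by default (a pooled-read variant is exposed),
because the headline figure is an average of library-level ratios.
Linearity regresses the 5hmC-probe read proportion on spike
concentration, defined as spike mass / input mass (fg/ng) — the only
dimensionally coherent reading of "concentration within cfDNA".

## 3. Differential model

Per-feature counts follow NB(μ_ij, α_j), log μ_ij = log s_i + x_i′β_j.

- **Size factors** s_i: median over all-nonzero features of
  count / geometric mean (median-of-ratios).
- **Design**: intercept, categorical covariates (age group in
  {<20, 20-55, >55}, technician), and the status contrast as the last
  column. Paired tumor/adjacent designs use technician plus
  patient-renumbered-within-technician fixed effects (exactly two
  samples per patient, both under one technician; validated). Rank
  deficiency is an error naming the collinear columns.
- **Dispersions**: per-feature Cox–Reid adjusted profile likelihood
  (grid + golden-section on log α, floor 1e-8, ceiling 10). The CR
  adjustment (−½ log det X′WX) matters at n ≈ 30: unadjusted ML
  underestimates α and inflates Wald statistics. A parametric trend
  α(μ) = a0 + a1/μ is fitted by least squares, iteratively excluding
  features more than 2 log-units off the trend. Final dispersions are
  MAP estimates — the CR likelihood plus a normal prior (sd 0.5) on
  log α centered at the trend — rather than a weighted average of point
  estimates, so boundary MLEs (near-Poisson features) shrink to a
  sensible value instead of collapsing standard errors. Two exceptions:
  estimates > 2 prior-sd above the trend are kept as-is (dispersion
  outliers must not be shrunk down), and features that are genuinely
  under-dispersed (ML at the floor with normalized-count variance below
  half the mean, e.g. constant counts) stay at the floor.
- **Wald test**: β̂_j(status)/SE from the batched IRLS fit at the final
  dispersions; log2 fold change f_j = β̂/ln 2 (no shrinkage — the
  selection thresholds apply to plain f_j). The statistic is referred
  to a **t distribution with residual df** by default. With a normal
  reference and ~33 samples, measured tail inflation (P(|z| > 4) ≈ 1e-3
  vs nominal 6e-5) produced a realized null FDR of 0.25–0.30 at nominal
  5% in 20-simulation experiments; the t reference restores control
  (realized FDR 0, per-test type-I error 0.045). `wald_dist="normal"`
  recovers the asymptotic convention.
- **Selection**: q < 0.05 (BH step-up) and |f_j| > log2(1.2), either
  direction. Zero-count features get NaN sentinels and are excluded
  from the BH family. Cook's-distance outlier handling and independent
  filtering are deliberately not implemented.

## 4. Frozen rlog normalization

The rlog transform computes v_ij = log2(K_ij/s_i + 0.5) and shrinks it
toward the feature's cross-sample training mean m_j with weight
w_j = 1/(1 + c·α_trend(μ_j)), c = 5: low-count features, whose
trend-predicted dispersion is dominated by Poisson noise, are pulled
harder; high-count features are left within 0.05 of the plain log. The
transform is monotone in the count and maps a constant feature to a
constant.

Fitting freezes the reference: per-feature log geometric means (for
size factors of new samples), shrink targets m_j, trend coefficients
and per-feature α_trend, and the pseudocount. Applying the reference to
new samples computes their size factors against the *training*
geometric means and reuses the frozen targets/weights — no statistic is
re-estimated from test data, mirroring the clinical constraint that
test batches arrive with unknown, case-skewed composition. Applying a
reference to its own training data reproduces the fit exactly.

## 5. Classifier

Penalized logistic regression minimizing

(1/N) Σ_i [log(1+e^{η_i}) − y_i η_i] + λ Σ_j ν_j (α|β_j| + (1−α)β_j²/2).

- **Penalty factors** ν_j = 1/max(|f_j|, ε), ε = 0.01, rescaled to mean
  1: loci with large training effect sizes are more reproducible and
  are penalized less. The functional form is the package's reading of
  that rationale and is pluggable.
- **Solver**: cyclic coordinate descent on the IRLS quadratic
  approximation, warm starts along a 100-point log-spaced λ path from
  λ_max = max_j |⟨x_j, y−ȳ⟩|/(Nαν_j) down to 1e-3·λ_max; weights
  floored at 1e-6; convergence when the maximum coefficient change
  < 1e-9 (inner) / 1e-8 (outer). The kernel is numba-compiled with a
  pure-Python fallback. On random small problems the attained objective
  matches generic numerical optimization to ~1e-13.
- **λ**: 10-fold stratified, seeded CV on held-out binomial deviance;
  λ_1se is the largest λ within one SE of the minimum.
  `n_folds == n` runs plain leave-one-out (a single-sample fold cannot
  be stratified).
- **α**: grid search (default 0.05–0.95 in steps of 0.1) maximizing
  AUC on a disjoint validation batch; ties go to the smaller α
  (the more ridge-like, more stable model).
- **Features standardized** to training mean/sd; the model serializes
  to JSON (coefficients, standardization stats, embedded normalization
  reference) and reloads to bit-identical predictions. Cancer is called
  at probability strictly > 0.5.

## 6. Evaluation and enrichment statistics

AUC is trapezoidal (ties count ½); the operating cutoff maximizes
sensitivity + specificity over all score midpoints, ties resolved
toward higher sensitivity. The Cochran–Armitage trend statistic uses
T = Σ x_i(r_i − n_i p̄), Var T = p̄(1−p̄)[Σ n_i x_i² − (Σ n_i x_i)²/N]
with equally spaced integer scores by default (no continuity
correction; a label-permutation p-value is exposed). Sample clustering
uses 1 − Pearson r with average linkage.

Percentile-overlap enrichment takes the top ⌈p/100·N⌉ genes of two
rankings (ties broken by stable gene id); fold = |A∩B|·N/(|A||B|); the
p-value is the hypergeometric upper tail. The neighbor-correlation null
correlates adjacent genes' log2 fold changes within chromosomes and
compares against values recomputed after shuffling gene positions
within each chromosome (default 1 000 shuffles; add-one empirical p so
p > 0 always).

## 7. Synthetic-data generator

Per-gene effects live on the natural-log scale: locus effects
(sd 1.5), per-tissue effects (sd 0.8), and disease effects (sd 0.5,
nonzero on a configured gene subset placed in contiguous blocks of mean
length 8 so the field keeps its chromosomal autocorrelation). Locus,
tissue and disease fields follow a stationary AR(1) process along gene
order within each chromosome (default ρ = 0.7), emulating the
region-wise behavior of 5hmC changes. The sd hierarchy
locus > tissue > disease encodes the observation that tissue identity
dominates disease status.

A cancer plasma sample with tumor fraction φ has natural-scale mean
(1−φ)·background_j + φ·tumor_j, where tumor_j carries the tumor-site
tissue effect plus the disease effect; controls are pure background.
φ ~ U(0.05, 0.2) by default — the mixture fractions are illustrative
(chosen as plausible for detectable-but-diluted tumor shedding), not
calibrated to any measurement — and stage labels are assigned in
increasing-φ order so stage-trend analyses have something to find.
Counts are NB with dispersion 0.05 at per-sample lognormal library
sizes (mean 1e6, sd 0.2 on the log scale), after a per-technician
multiplicative log-normal gene-wise batch factor (sd 0.15) that
exercises the covariate adjustment. Tissue pairs emit tumor (φ = 1) and
adjacent samples per patient, nested under technicians.

Spike-in libraries allocate reads proportionally to capture-weighted
mass (probe masses in fg against cfDNA input in ng), so the expected
5hmC-probe proportion is nearly linear in spike concentration and
decreasing in input mass; capture efficiencies default to 0.9 (5hmC)
vs 0.0225 (unmodified), giving pull-down folds in the tens.

**What the generator does not emulate**: fragment-size distributions
and end motifs, sequence composition, copy-number variation, 5mC
contamination of the pull-down, and batch effects that alter the
mean–dispersion relationship rather than gene-wise means. Passing tests
therefore demonstrate the pipeline's statistical behavior under its own
model assumptions, not performance on real plasma — with the default
effect sizes the synthetic classification task is easier than real
cohorts, and held-out AUCs near 1.0 should be read accordingly.

## 8. Simulation scales

The shipped end-to-end run uses 5 000 genes (4 chromosomes × 1 250),
500 disease genes, and batches of 15 vs 18 (discovery), 24 vs 35
(validation) and 32 vs 37 (held-out test). Null calibration uses 20
cohorts of 15 vs 18 over 1 000 genes with φ = 0 and technician effects
on; realized FDR is the mean per-simulation false-discovery proportion
V/max(R,1) — under a global null this estimator is a rare-event
indicator, so its 20-replicate average is itself noisy. Enrichment
asymmetry uses 2 000 genes, 200 disease genes, 15 vs 18 plasma and 20
tissue pairs; the tissue-level ranking is the mean log2 normalized
count over the *adjacent* samples, the baseline tissue level
unconfounded by the disease effect. Permutation-null calibration uses
300-gene chromosomes (200 replicates at 499 shuffles for uniformity;
20 at ρ = 0.7 for power).

## 9. Known limitations

- Dispersion trend is the two-parameter a0 + a1/μ family; data whose
  dispersion rises with the mean will be under-fit.
- The Wald t reference is a finite-sample heuristic, not an exact
  distribution; likelihood-ratio tests would be a principled (slower)
  alternative.
- The rlog shrinkage weight is a one-parameter approximation of full
  empirical-Bayes shrinkage; it stabilizes variance but does not
  reproduce any particular reference implementation bit-for-bit.
- `percentile_enrichment` assumes both rankings cover the same
  universe; partial universes are intersected silently.
- The generator's stage assignment is a deterministic function of
  tumor fraction; real staging is noisier.
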