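# Methods

## Scope and model

`immunocorr` analyses the association structure between a small set of hub
proteins (complement C4A, C4B, C1QA measured in CSF) and a larger
inflammation panel measured in CSF and plasma, contrasted between two
diagnostic groups (healthy controls, HC; first-episode psychosis, FEP).
All protein values are treated as log2-scale relative abundances.
The pipeline assumes subjects are independent, that confounding by age, sex,
BMI and antipsychotic medication is linear on the (rank) scale, and that
missingness is ignorable for pairwise-deleted correlations.

## Partial Spearman correlations

The partial Spearman correlation is defined by rank-then-residualize: both
variables are rank-transformed (average ranks for ties) over the complete
cases of the (x, y, covariates) tuple, residualized on an intercept plus the
covariates by least squares, and the Pearson correlation of the residuals is
returned. The p-value uses the t approximation with df = n − 2 − k. This
construction is exactly reproducible by a brute-force oracle (explicit rank
vectors, normal equations), which the test suite exercises on 200 random
small instances at 1e-10 tolerance.

Deletion policy: complete cases listwise *within* one (x, y, covariates)
tuple, pairwise *across* different correlations. A single correlation cannot
mix rows with missing covariates; different panel proteins may use different
subject subsets. Covariate columns constant on the analysis rows (the
medication flag is identically 0 in HC) are dropped with a logged warning and
k is decremented; a rank-deficient design after the constant drop raises an
error naming the collinear columns. Results with fewer than k + 4 complete
cases are flagged unusable rather than raising, so profile-level callers can
skip and count.

Method selection, where enabled (`method_policy="auto"`), applies
Shapiro-Wilk to each variable and uses Pearson only when both look normal at
alpha 0.05 (configurable); the profile-level default is fixed Spearman, which
is also what the permutation machinery assumes.

## Group contrasts

Per-protein correlation differences Δr = r_FEP − r_HC are tested with
Fisher's z using each pair's own effective sample sizes:
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3−k) + 1/(n₂−3−k)). The k-correction of
the variance is the standard extension for partial correlations and reduces
to the classical formula at k = 0. Each pair uses its own n_eff (matching
the pairwise-deletion policy) rather than the global group n.

Slope contrasts fit per-group OLS of y on intercept + x + covariates,
extract the slope on x and its SE, and compare with
t = (b₁ − b₂)/√(se₁² + se₂²) against a t reference with Welch–Satterthwaite
df (df and both SEs are reported, so a normal-reference reading is also
reconstructible).

Whole-distribution comparisons of two sets of coefficients use the
two-sided Wilcoxon rank-sum (Mann-Whitney U) test, exact at small tie-free
sample sizes.

## Permutation profile-shift tests

The central inference. For a hub and panel, each group yields a profile of
partial Spearman correlations; two statistics summarise the between-group
difference:

- directional: mean over proteins of (r_FEP − r_HC);
- absolute: mean over proteins of |r_FEP − r_HC|.

Null distributions come from permuting diagnosis labels across subjects —
each subject's covariate row and both compartments' values travel together;
only the label moves, so the null is exchangeability of diagnosis given the
joint data. The full per-group profile computation is repeated for every
permutation. The panel is held fixed (no resampling over proteins): the test
treats the panel as the support of the estimand.

Conventions:

- Empirical p-values use the add-one correction
  (1 + #{null ≥ observed})/(n_perm + 1) and can never be exactly zero.
- The directional test is one-sided toward a positive shift by default
  (`alternative="less"` flips the tail); this is the convention under which
  a negative shift yields a large p. The absolute test always uses the upper
  tail of the magnitude statistic; its null expectation is positive, so the
  reported `observed` is centered by the null mean while `observed_raw`
  feeds the tail count (no double-centering).
- A z-score — (observed_raw − null mean)/null SD — is reported alongside
  p_emp so either convention can be compared.
- Both modes can be computed on the same permutation stream
  (`directional_and_absolute`), making the pair directly comparable.
- n_perm defaults to 10,000 and must be ≥ 100. Proteins with too few
  complete cases in a permutation are skipped with a counter; if more than
  10% of protein×permutation cells are skipped the test aborts with a
  diagnostics message.

Implementation: with complete data the per-permutation profile pair is
vectorised (column-wise ranking, a QR projection per group, then normalized
dot products), which is what makes 1000-permutation tests run in well under
a second at n = 120 and keeps the calibration simulations tractable. A
missing-tolerant path (per-protein complete cases) is used automatically
when the input contains NaNs.

## FDR and the univariate dispatcher

Multiple testing uses the two-stage Benjamini–Krieger–Yekutieli linear
step-up at q = 10%: stage 1 at q′ = q/(1+q) estimates m0 = m − r1; if
r1 = 0 nothing is rejected, if m0 = 0 everything is; otherwise stage 2
reruns the step-up at q′·m/m0. One analysis family = one hub's panel of
delta-profile p-values (or one component-by-scale grid); family definitions
are explicit at call sites. Note the two-stage procedure dominates the plain
step-up at its corrected level q′, not at raw q: when stage 1 rejects
nothing the procedure stops even if the raw-q step-up would have rejected.

The univariate group-difference dispatcher checks normality first
(Shapiro-Wilk per group; failure routes to Mann-Whitney — a variance test
on non-normal data would be moot), then Brown-Forsythe (median-centered
Levene) for variance equality (failure routes to Welch), else Student's t.
The branch taken is always returned.

## Networks and bootstrap

The complement network is all pairwise zero-order Spearman correlations
(no regularization, no covariate adjustment), pairwise deletion, within each
group separately. Edge stability uses the nonparametric bootstrap: subjects
resampled with replacement within group (10,000 resamples by default,
minimum 200), percentile 2.5/97.5 CIs per edge. Percentile intervals were
chosen over BCa as the simplest defensible interval and are labeled as such
in output. Resamples in which a node is constant (Spearman undefined) are
redrawn with a logged counter.

## PCA and clinical correlation

PCA is computed by SVD of the centered, unit-variance-scaled protein matrix
(a correlation-matrix PCA). Complete-case subjects by default; an optional
per-protein mean-imputation mode is recorded in the result object. The first
four components are retained; variance fractions are reported over all
components and sum to one. Eigenvector sign is fixed by making each
component's largest-magnitude loading positive. Complement hubs and panel
proteins enter one joint PCA; the clinical-correlation analysis is run on
FEP subjects (symptom scores exist only there). Component scores are
correlated with PANSS Positive/Negative/General and BKY flags are attached
across the component×scale family.

## Cross-compartment concordance

Per protein, CSF and plasma levels of subjects with paired samples are
correlated within each group — Spearman, unadjusted by default (a covariate-
adjusted switch exists), significance highlighted at raw two-sided p < 0.05
with BKY flags additionally emitted. The overlap summary counts significant
proteins per group and their intersection.

## Synthetic cohorts

The generator emulates the study design the pipeline targets: 90 HC and 113
FEP subjects by default, 48 panel proteins, three hubs, and optional
per-compartment subsampling of panel coverage (e.g. 35 HC / 63 FEP) to
emulate partial assay coverage; hubs remain measured in everyone.

Latent model: per group, a target correlation matrix over (hubs + panel) is
assembled from per-hub mean (or per-protein) hub-panel targets plus Gaussian
jitter, hub-hub targets, and an equicorrelated panel block, then projected
to the nearest valid correlation matrix by eigenvalue clipping at zero and
diagonal renormalization, iterated to convergence (idempotent within 1e-10).
Multivariate normal latents are drawn from the projected matrix — a Gaussian
copula on the log2 scale. Spearman statistics are invariant to monotone
marginal transforms, so Gaussian marginals lose no generality for the
rank-based pipeline. Default hub-panel means encode the motif the pipeline
is designed to detect (C4A negative-leaning in HC, positive in FEP; C4B and
C1QA positive in both); default hub-hub targets encode the observed
complement geometry (C4A–C1QA 0.41 in HC collapsing to 0.09 in FEP,
C4B–C1QA ≈ 0.48 in both, C4A–C4B ≈ 0.14).

Covariates: age and BMI are truncated normals with group-appropriate means,
sex is Bernoulli (encoded F=0/M=1 for covariate arithmetic), medication is
identically 0 in HC and Bernoulli(77/113) in FEP. A shared covariate loading
adds confounding to every protein, so marginal correlations exceed partial
ones — which the test suite verifies downstream adjustment removes. Plasma
panel values couple to the CSF latents at `cross_compartment_corr` (default
0.10, i.e. near-zero concordance). Missingness is MCAR at `missing_rate`
(default 0.02); an MNAR mode with detection-limit-like behaviour
(missingness odds rising at low abundance) exists but is off by default.
PANSS-like scores are integer truncated normals on the instrument ranges
(7–49, 7–49, 16–112); `inject_clinical_association` rank-maps them onto a
latent correlated with a chosen component axis, preserving marginals
exactly.

What the generator does *not* emulate: assay plate effects and interplate
normalization artifacts, heavy-tailed or mixture marginals, shared-batch
correlation, longitudinal sampling, and genotype-driven structure (C4 copy
number). Passing tests therefore demonstrate correctness and calibration of
the statistics under a clean elliptical-copula world, not robustness to
assay pathology.

### Calibration scenarios

In the calibration and power simulations, a between-group profile shift of
Δ is realized symmetrically (HC target −Δ/2, FEP target +Δ/2), and the
sign-balanced magnitude scenario as HC ∓0.2 / FEP ±0.2 over panel halves.
Splitting the shift keeps both groups' target matrices inside the
positive-semidefinite cone, so the injected between-group delta equals the
nominal value exactly instead of being shrunk by the projection. Null
calibration cohorts use identical targets in both groups and no covariate
loadings, making diagnosis labels exactly exchangeable. Problem sizes for
these simulations (60 subjects/group, 20 proteins, 1000 permutations;
100–200 replicate cohorts; bootstrap coverage at n = 100 with 2000
resamples) were chosen as the smallest scales at which the binomial noise
of a rate estimate is comfortably inside the acceptance bands.

## Numerical choices and edge cases

- Ties: average ranks throughout; tie-free identities (e.g. Spearman
  invariance under strictly increasing transforms) are exact.
- Coefficients are clipped to [−1, 1] after residual correlation to guard
  against floating-point overshoot; Fisher z returns signed infinity at
  |r| = 1.
- Constant vectors: correlation results are flagged unusable (not raised)
  inside profiles; Shapiro-Wilk-based deciders raise, since the test is
  undefined.
- Determinism: every stochastic routine takes an integer seed and uses an
  isolated `numpy.random.Generator`; the end-to-end report bundle is
  byte-identical across runs, output locations and the `--threads` flag
  (computation is single-threaded; the flag is an interface contract).
- The run manifest records config, seed, package version, realized group
  sizes and every convention switch, and deliberately contains no
  timestamps or absolute paths.

## Known limitations

- The permutation test recomputes ranks per permutation (required, since
  ranking is within-group); with heavy missingness it falls back to a much
  slower per-protein path.
- Fisher-z contrasts assume approximate normality of atanh(r); at very
  small n_eff the permutation machinery is the more trustworthy route.
- The MNAR mode is a simple abundance-dependent thinning, not a mechanistic
  detection-limit model.
- p-values for partial correlations use the t approximation; no exact
  permutation option is exposed at the single-pair level.
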