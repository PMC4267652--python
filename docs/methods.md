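# Methods

## The inference problem

Promoter-level ChIP-Seq gives, for each of ~10⁴ promoters, the occupancy
of a panel of chromatin modifiers (CMs) and histone modifications (HMs),
plus an input-control track and expression tag counts. The goal is a
signed bipartite network of CM–HM interactions that cannot be explained
away by the other measured tracks. Two estimators with complementary
failure modes are intersected: a per-HM elastic-net regression on all CMs
(robust to correlated CMs, blind to correlated HMs) and a sparse
partial-correlation network over all tracks (conditions on everything,
but can explain away true edges inside tight complexes). The intersection
is deliberately conservative: high specificity at the cost of
sensitivity.

## Preprocessing

* **Window counting.** Reads are single 5′ positions counted into
  0-based half-open promoter windows (±2000 bp around the TSS, so 4000 bp
  wide); a read in overlapping windows counts in each; strand is ignored
  (windows are symmetric around the TSS). Fragment extension and
  alignment are upstream concerns.
* **Promoter filter.** A promoter is kept iff at least one ChIP (HM or
  CM) track strictly exceeds the input count there. Expression tracks do
  not participate: the enrichment comparison is between ChIP samples and
  their input control. The filter runs before normalization, so the
  median ratio is computed over the retained promoters.
* **Median-ratio normalization.** Per ChIP track, r_i = (S_i+1)/(C_i+1)
  and m = median(r_i); output r_i/m. The median over an even count of
  promoters is the midpoint of the two central order statistics. The
  input track is consumed; expression tracks pass through (tag counts
  have no input control).
* **Log/z transform.** Normalized ChIP values are strictly positive and
  logged directly; averaged expression counts can be zero, so they get a
  pseudo-count of 1 (configurable) first. Columns are centered and scaled
  to unit SD with the n−1 denominator. Constant columns are an error
  naming the track.
* A state flag (`raw_counts → normalized → standardized`) enforces this
  order; out-of-order calls fail loudly.

## Elastic-net arm

Objective: RSS + λ[(1−α)‖β‖₁ + (α/2)‖β‖₂²], intercept unpenalized. The
mixing convention puts the L1 weight on 1−α (so α is the *quadratic*
share; the reverse of the scikit-learn / glmnet convention — internally
l1_ratio = 1−α, sklearn-alpha = λ/(2n), an exact reparameterization). The
L2 term is squared: the constraint form that motivates the method writes
the unsquared norm but defines ‖β‖₂² immediately after; the squared form
is the standard smooth, convex elastic net, and it is what path solvers
optimize. The constraint radius t and the Lagrangian λ are dual; we work
in the penalized form throughout.

**α selection.** Grid {0.01, 0.1, …, 0.9, 0.99} (the interval endpoints
are fixed; the interior lattice is our choice). For each α, 10-fold CV
over a 50-point λ path; the per-α score is the best mean CV MSE on the
path. The one-standard-error rule admits every α whose score is within
one SD (across folds, at the overall minimizer) of the minimum, and the
*smallest* admissible α — the most L1-heavy, hence sparsest — is chosen;
ties break to the smaller α. MSE rather than summed RSS is used so folds
of slightly unequal size weigh equally.

**Coefficient summaries.** With α fixed, 10 outer folds; within each
training part an inner 5-fold CV picks λ on the path; the fitted
coefficients and the held-out R² are recorded per fold, then averaged
(mean, SD across folds). Folds with a constant target are skipped with a
warning.

**Selection rule.** Per HM, let μ and σ be the mean and sample SD of the
|mean coefficient| over all CMs; CM selected iff |coef_mean| ≥ μ + σ and
σ > 0 (a floating-point-degenerate σ ≤ 1e−12·max(1, max|coef|) counts as
zero). Absolute values make the rule symmetric for activating and
repressive interactions; a `signed` convention (deviation from the signed
mean) is available since the rule's wording is sign-ambiguous.

## SPCN arm

Tracks are rank-transformed (average ranks on ties) — a conditional
Spearman analogue robust to heavy-tailed enrichment. The full pairwise
partial-correlation matrix comes from the precision matrix,
pcor(i,j) = −Ω_ij/√(Ω_ii Ω_jj), which equals the correlation of
residuals after regressing each variable on all others; the test suite
asserts this equivalence to 1e−8 on random data, and a near-singular
covariance (condition number > 1e10) is ridge-stabilized by
1e−6 × mean-diagonal with a warning. Significance per pair: Fisher
z-transform with effective degrees of freedom n − (p−2) − 3 (p−2
conditioned variables), two-sided normal p-value, Benjamini–Hochberg
q-values over all pairs. Sparsification recomputes ranks, partial
correlations and q-values within each of k = 10 training folds (no
leakage from held-out promoters) and retains an edge iff q ≤ 0.05 in
every fold with one consistent sign — and on the full data, so the
retained set is a subset of the significant pairs. The all-folds rule is
one concrete, conservative instantiation of CV-based sparsification;
prediction-accuracy-driven variants exist, and k and the q threshold are
exposed.

## Intersection and signs

An edge (CM, HM) enters the final network iff the CM passed the
deviation rule for that HM **and** the pair survived the SPCN filter.
The reported sign is the partial correlation's (conditioned, hence
closest to direct); the elastic-net coefficient and a sign-concordance
flag are kept as provenance, and discordant edges are flagged rather
than dropped (no principled discard rule exists). Evaluation against a
known truth reports precision, recall (optionally restricted to the top
weight-magnitude tercile of true edges), and sign accuracy among true
positives.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not the underlying biochemistry:

* CM latent log-signals: z_c = √ρ·f_g + √(1−ρ)·e_c with a shared factor
  per complex, so same-complex CMs correlate at ρ
  (`within_complex_corr`, default 0.7 — strong complex co-occupancy that
  still leaves members distinguishable).
* HM latents: h = W z + N(0, noise_sd_hm); W is sparse
  (`edge_density` = 0.2), magnitudes uniform on [0.4, 1.2] with random
  sign, at least one parent per HM.
* Expression replicates (two, to exercise replicate averaging):
  y = v·h + N(0, noise_sd_expr), with v scaled analytically so the
  expression latent has unit variance (keeps tag counts on a realistic
  scale for any network size).
* Observation: a per-promoter coverage bias b ~ lognormal(0,
  `input_bias_sd` = 0.5) multiplies every track's Poisson mean
  (`count_depth`·b·exp(latent)); the input track is Poisson(count_depth·b).
  This is exactly the nuisance the median-ratio normalization removes.
* Two conditions ("cell types") share W and v; condition B multiplies
  each CM's latent by an activity scalar (lognormal, sd 0.2 on the log
  scale). Latent draws depend only on the truth seed, so conditions with
  equal activities differ purely in count noise.

Defaults (5000 promoters, 20 CMs in 4 complexes, 8 HMs, depth 50,
noise_sd_hm 0.6, noise_sd_expr 0.4) were set so that cross-validated
HM-on-CM R² lands in 0.5–0.9, the range typical of promoter co-occupancy
panels; under these conditions the intersected network reaches precision
≈ 1 with full recall of the strongest tercile of true edges.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: unobserved confounders (CMs or HMs missing
from the panel), nonlinear or saturating responses, antibody efficiency
differences, copy-number or mappability artifacts beyond a smooth
coverage bias, spatial correlation along the genome, and feedback from
expression to chromatin state. Real-data edge lists remain hypotheses.

## Numerical choices and degenerate inputs

* Held-out R² = 1 − RSS/TSS with TSS centered on the held-out fold's own
  mean; an intercept-only model therefore scores ≤ 0 up to sampling
  noise. A zero-TSS fold yields NaN and is excluded from the mean.
* CV folds: seeded uniform random partitions without stratification,
  recorded in every report; paired comparisons (HM vs CM vs joint
  expression models) share one partition.
* Transfer evaluation standardizes each condition separately and fits
  once on all training promoters. Per-HM transfer R² can drop well below
  the within-condition CV R² when that HM's driving CMs shifted activity
  most; the headline transfer property is the margin averaged over HM
  targets per study.
* Singular OLS designs fall back to the least-norm solution with a
  warning; elastic-net fits use coordinate descent at tol 1e−10 for the
  single-fit API and 1e−6 along CV paths.
* Window counting logs (and ignores) reads on chromosomes without
  windows; empty matrices, constant tracks, unknown conditions, missing
  tracks and out-of-order pipeline calls raise typed errors.

## Problem sizes used in the checks

The automated checks run the pipeline at the default study size (5000
promoters) over ten seeds, the partial-correlation equivalence on 100
random sets (n = 200, p ∈ 3..8), and the null calibration on 200
simulations (n = 500, p = 10); unit tests use a 1200-promoter instance
of the same conditions.

## Known limitations

* The α-selection sentence this implements ("within one SD of the
  minimum, prefer sparsity") is one reading of an ambiguous rule; the
  admissible-set logic is isolated in `select_alpha` if another reading
  is wanted.
* The SPCN sparsifier is significance-driven; accuracy-driven
  sparsification is not implemented.
* Expression is never input-normalized (tag counts have no input
  control); if a matched control exists it must be handled upstream.
* n ≤ p track panels are rejected rather than estimated with a shrinkage
  precision estimator (graphical lasso is out of scope).
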