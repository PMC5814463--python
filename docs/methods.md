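# Methods

This note documents the statistical procedures implemented in
`sepsisprog`, the assumptions behind them, the defaults and why they
were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions made where the underlying
publications are silent.

## Signatures and scoring

A gene signature is a named pair of disjoint gene-symbol sets: `up`
(higher in patients dying within 30 days) and `down` (lower).  Gene
identity is the official symbol string after upper-casing; no alias
resolution is attempted, because the published predictors are defined
on symbols and symbol-level matching keeps scoring deterministic and
free of external databases.  The four built-in predictors (Duke 5
up / 13 down; Sage LR 9/9; Sage RF 13/4; Stanford 8/4) are stored as a
versioned GMT fixture guarded by a SHA-256 checksum; their directional
union has 58 genes (31 up, 27 down) with no up/down conflicts.  Legacy
symbols in the source lists (e.g. EMR3, IL8, SEPP1) are preserved
verbatim rather than remapped, since any remapping policy would be a
guess about upstream platform annotation.

The signature score of sample *s* on log2 expression *x* is

    S_s = mean_{g in up}(x_gs) − mean_{g in down}(x_gs),

the log2 form of the difference of geometric means.  Missing signature
genes are dropped (with a warning and a per-side usage count), not
imputed: the score is parameter-free, so renormalizing over the genes
present is the only internally consistent choice.  Scores are computed
on raw log2 values without within-cohort gene standardization; the
score is invariant to per-sample location shifts, and any per-cohort
centering is a monotone within-cohort transformation that leaves every
rank-based downstream statistic unchanged, so standardization would add
a tunable step without changing conclusions.  Linear-scale input is
rejected with instructions; the `to_log2` helper floors values at 2^-10
before the log to avoid −∞ on non-positive intensities.

Cell-type enrichment reuses the same formula on a sorted-cell reference
profile.  Its null distribution is generated by drawing random same-size
up/down gene sets from the profile's gene universe; the two-sided
permutation p-value is `(1 + #{|null| ≥ |observed|}) / (n_perm + 1)`,
which is never exactly zero and is uniform under the null.

## Preprocessing

Inputs are assumed summarized (probe-level intensities or gene counts);
platform background correction is an upstream concern and is not
re-implemented.  Probe-to-gene collapse takes the arithmetic mean of a
gene's probes per sample; probes mapping to more than one gene are an
error rather than being duplicated into both genes, avoiding double
counting (the source pipelines are silent on this case).

Quantile normalization makes every sample's sorted value vector equal
the cross-sample mean of sorted vectors.  Ties within a sample receive
the mean of the reference values across their tied ranks (the dominant
convention, e.g. limma's default); note that with ties the
"identical sorted columns" identity holds only approximately — the
tie-free case satisfies it to machine precision, and applying the
transform twice equals applying it once.

RNA-seq counts go through a voom-style transform:
`log2CPM = log2((count + 0.5) / (libsize + 1) × 1e6)` (the standard
offsets; the named method does not print them), a lowess trend of the
square-root residual standard deviation against the per-gene mean
log2-CPM, and a per-observation precision weight equal to the inverse
predicted variance.  The pipeline's default multiplies the weight into
the log2-CPM value — an unusual use of precision weights, retained
because it is how the original analysis constructed its final
expression values — and `apply_weights=False` returns plain log2-CPM
with the weight matrix alongside.  For negative-binomial-like counts
the log-scale variance `≈ 1/μ + φ` falls with the mean, so the fitted
weights rise with expression; the tests assert this direction.

Sample inclusion keeps draws within the first 48 h after admission
(closed interval `[0, 48]`; the source phrase "first 48 h" has no
boundary semantics, and the closed reading keeps the printed boundary
samples), keeps samples with unknown sampling time (logged), and can
drop samples with missing 30-day outcome.  Every exclusion is recorded
with its reason.

## Re-trainable predictors

Feature selection follows the two-phase design: per cohort, each gene
gets a Welch t-statistic (non-survivors minus survivors) mapped through
its t distribution to a standard-normal z; cohort z-scores are combined
by Stouffer's method weighted by √n; genes with |combined z| above a
configurable threshold (default 4.0) are selected.  Cohorts with one
outcome class are excluded with a warning.  The exact statistics and
thresholds of the originally published models are supplementary
material not reproduced here; Welch + Stouffer is the standard
heterogeneity-tolerant choice and the threshold is recorded in the
result object.

The penalized logistic regression standardizes features and fits an
elastic net (l1_ratio 0.5) whose penalty is chosen by stratified 5-fold
cross-validation maximizing AUROC with the one-standard-error rule:
among penalties within one SE of the best mean CV score, the strongest
is used.  The one-SE rule matters because AUROC plateaus once the
signal is captured, and the plateau's weak end keeps dozens of tiny
noise coefficients; the sparse end of the plateau concentrates the
nonzero weights on true signal (the recovery test measures this).  The
random forest uses 1000 trees, √p features per split and class
weighting.  Class imbalance is always handled by weighting, never
resampling, for determinism; both models are exactly reproducible from
their recorded seed, and `training_meta` stores the hyperparameters
actually used (including the chosen penalty).

The ensemble averages within-cohort rank-normalized model scores
(mid-ranks, rank/(n+1)).  Rank normalization is used because the four
models emit incommensurate scales (log2 differences vs probabilities)
and cross-model comparisons in this setting are rank-based; it makes
the ensemble invariant to any strictly monotone rescaling of an input
model.

## Evaluation statistics

Throughout, higher score ⇒ higher predicted mortality risk, and death
is the positive class.

**AUROC** is computed by the rank formula, which equals trapezoidal
integration of the empirical ROC and the pairwise concordance
probability with ties counted ½ (the tests verify exact agreement with
an exhaustive pair oracle).  The 95% CI is a stratified bootstrap
(positives and negatives resampled separately; 2000 replicates by
default, seeded).  A bootstrap was chosen over an asymptotic formula
because the evaluated cohorts can be very small and the CI method in
the source material is unstated.

**AUPRC** is the trapezoidal area over recall-ordered
precision–recall points, anchored at recall 0 with the first achievable
precision.  On uniformly random scores it concentrates at the
prevalence.

**Summary ROC (Kester & Buntinx family).**  Every cohort's achievable
operating points (excluding the two trivial all-or-nothing points) are
mapped to `S = logit TPR + logit FPR`, `D = logit TPR − logit FPR`;
degenerate proportions at 0 or 1 are continuity-corrected by half a
count before the logit.  A linear fit `D = a + bS`, weighted by cohort
size, selects the family member; the curve is back-transformed on an
FPR grid via `logit TPR = (a + (1+b)·logit FPR) / (1−b)` and integrated
trapezoidally.  The CI bootstraps whole cohorts.  The fit is ordinary
weighted least squares — the original estimation details sit behind a
citation — and is isolated in one function so the fitting method can be
swapped without touching the transform or the integration.  With one
cohort (or identical cohorts) the summary area reproduces that cohort's
smoothed area to within 0.02; a zero fitted slope yields a curve
symmetric about the anti-diagonal.

**Operating thresholds.**  "Nearest sensitivity above target" is read
over the discrete achievable set: the minimal achievable sensitivity
strictly greater than the target, ties broken by higher specificity.
2x2 test characteristics report PPV/NPV as missing (not zero) when a
denominator is empty.

**Severity comparison.**  Three logistic regressions (severity only,
gene score only, both without interaction) are fitted by maximum
likelihood; samples without a severity value are dropped and counted.
On perfect separation or non-convergence the fit falls back to a small
ridge penalty (C = 100) with a warning — common on small cohorts where
a score separates the classes.  The AUROC of each model's fitted
probabilities is reported, plus the training log-likelihoods (the
nested-model inequality is only guaranteed for exact MLE fits, and the
result object records whether a penalized fallback was used).

**Continuous NRI.**  `event = P(new > old | death) − P(new < old |
death)`; `nonevent = P(new < old | survival) − P(new > old |
survival)`; ties contribute zero; `cNRI = event + nonevent ∈ [−2, 2]`.
Inference defaults to the asymptotic normal form with component
variances `(p_up + p_down − (p_up − p_down)²)/n` summed over the two
strata; a stratified-bootstrap percentile CI is available behind a flag
for small cohorts.

**Model agreement.**  Per-dataset AUROCs are compared by two-sided
paired t-tests (a zero-variance difference vector is flagged as
degenerate: p = 1 when the difference is zero, otherwise reported as
below machine resolution).  Inter-model correlation is Spearman's rho
on within-cohort mid-ranks pooled across cohorts.  Consensus
classification labels each patient by how many of the four models
classified them correctly at that model's 90%-sensitivity threshold:
0 → always misclassified, 1–2 → no consensus, 3–4 → consensus.
Correctness is pooled across cohorts by default (per-cohort thresholds
behind a flag, since the pooling level in the source is ambiguous).

**Longitudinal slopes.**  Per patient with ≥2 time points, the OLS
slope of score against time (per day) and the mean score; groups are
compared by Welch t-tests on slopes (trajectory) and on means (level).

## Gene-set over-representation

The background defaults to the genes shared by all analyzed cohorts
(user-overridable).  Sets are intersected with the background, then
retained only if they overlap the predictor genes by at least 3 genes
and at least 10% of the intersected set size.  The test is the
one-sided hypergeometric upper tail (over-representation), verified in
tests against an exact rational tail enumeration; q-values are
Benjamini–Hochberg.  No pathway content ships with the package.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis
assumes, not any platform's intensity distributions:

- latent risk r ~ N(0, 1) per patient; death ~ Bernoulli(logistic(q_c + r))
  with the cohort offset q_c solved by Gauss–Hermite quadrature so the
  expected mortality equals the configured cohort rate;
- gene baselines ~ N(8, 1.5²) log2 units shared across cohorts; a
  per-cohort per-gene batch shift ~ N(0, τ²); +δ / −δ on the
  signature's up/down genes in non-survivors; observation noise
  N(0, σ²);
- severity = λ·r + (1−λ)·independent noise, min-max rescaled to an
  APACHE-II-like [0, 40] per cohort — severity and the transcriptomic
  signal are correlated only through the latent risk, which is exactly
  the regime in which a joint severity-plus-gene model can beat either
  covariate alone;
- a negative-binomial counts mode (gamma–Poisson, dispersion 0.2)
  exercises the RNA-seq preprocessing branch.

Defaults: 5 cohorts × 100 samples; cohort mortality rates (0.10, 0.18,
0.23, 0.30, 0.40), spanning the spread observed across the 21 real
cohorts around their 23.2% mean; δ = 1 log2 unit; σ = 1; τ = 0.5;
λ = 0.7; 200 noise genes; seed mandatory.  The acceptance-level checks
use the sizes stated with each property (5 × 200 cohorts for feature
recovery; 500 pooled samples per replicate for the effect-size sweep;
two cohorts of 500 for the binormal summary-ROC check).

What passing tests on these data do **not** show: robustness to probe
effects, platform-specific saturation, non-Gaussian intensity noise,
confounding between severity and batch, or real biological correlation
among signature genes (simulated genes are conditionally independent
given outcome).  Real-data performance claims are outside what the
generator can certify.

## Numerical choices and degenerate inputs

- Constant expression matrices pass through quantile normalization
  unchanged (warning).  Cohorts with a single outcome class are skipped
  per-statistic in the pipeline, with the reason recorded, rather than
  failing the run.
- Welch z-scores with underflowing t tails are clamped to ±38 (beyond
  double-precision tail resolution).
- The summary-ROC back-transform is undefined at fitted slope b = 1;
  this is raised as an error (it corresponds to a degenerate family
  member never produced by real operating points).
- Permutation p-values use the add-one convention and are therefore
  bounded below by 1/(n_perm + 1).
- All stochastic procedures (bootstraps, permutations, simulations,
  model fits) take explicit seeds and are bitwise reproducible.

## Known limitations

- The original fitted weights of the Sage LR/RF models were never
  published; the architectures here are re-trainable equivalents, not
  reproductions, and no attempt is made to recover the original gene
  selections from discovery data.
- CEL/IDAT parsing, gcRMA, normal-exponential background correction and
  ComBat co-normalization are out of scope; inputs must be summarized
  matrices.
- Mortality is modeled as a binary outcome (no time-to-event), matching
  the available annotations; no calibration metrics or DeLong tests are
  provided.
- The enrichment module tests over-representation only; expression-based
  set enrichment (GSEA/GSVA) is not implemented.
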