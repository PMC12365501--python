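# Methods

`tmtdiff` infers differential protein abundance from multiplexed,
isobarically labeled (TMT) proteomics experiments.  This note documents
the statistical model, the preprocessing and summarization steps, the
simulator used for validation, and the numerical and design choices a
user should know about.

## The data and its correlation structure

Quantification happens at the level of peptide-spectrum matches (PSMs):
each identified spectrum yields one reporter-ion intensity per channel,
i.e. per multiplexed sample.  Samples are pooled into mixtures; a mixture
is acquired in one or more MS runs (technical repeats or fractions).
Intensities are therefore correlated at several levels: within a mixture,
within a run, within a sample (the PSMs of one protein pool), and within
a spectrum.  Ignoring this structure understates uncertainty and inflates
false positives, which is the core problem the package addresses.

## Model

For one protein, the log2-transformed and normalized intensities are
modeled as a linear mixed model

    y = X beta + Z u + eps,     u ~ N(0, sigma^2 D),   eps ~ N(0, sigma^2 I)

where `X` holds the condition effects and any sample- or feature-level
covariates, and `Z` holds indicator blocks for the grouping factors of
the hierarchy -- mixture, run, sample (run x channel), and psm (spectrum)
-- each block with its own variance ratio `gamma_b = sigma_b^2 / sigma^2`
on the diagonal of `D`.

Two regularizations are optional and independent:

- **Ridge penalization of condition effects.**  The condition factor can
  be moved from `X` into `Z` as a full indicator block (no reference
  level dropped) with one shared variance component.  By the classical
  ridge/mixed-model equivalence, the REML estimate of that component sets
  the penalty `lambda = sigma^2 / sigma_cond^2` adaptively: proteins with
  no real condition signal get their fold changes shrunk toward zero,
  producing the characteristic spike of p-values at 1 for null proteins,
  while strongly differential proteins are barely shrunk.
- **Huber M-estimation.**  Observation weights `w_i = min(1, k / |r_i / s|)`
  with `k = 1.345` (95% Gaussian efficiency) and `s = 1.4826 x MAD` of the
  current conditional residuals, iterated to convergence (IRLS).  Each
  iteration refits the full REML problem under the current weights, warm
  started at the previous variance ratios.

### Estimation

Variance ratios are estimated by REML with `sigma^2` profiled out.  With
`T = [X | Z]`, `A = T'WT`, and `C = A + diag(0, 1/gamma)`, the profiled
criterion is

    (n - p) log(y'Py) + log|C| + sum_b q_b log gamma_b,
    y'Py = y'Wy - rhs' C^{-1} rhs .

It is minimized over log ratios, bounded in `[1e-10, 1e8]`, by L-BFGS-B
with the analytic gradient (the stationarity condition is the classical
REML fixed point per block), seeded by a bounded Brent search in the
single-ratio case, and finished by a few Newton steps on the gradient.
The gradient-based polish matters: the criterion itself is reproducible
only to ~1e-10, and the package promises closed-form agreement (ordinary
least squares, balanced one-way ANOVA estimators, pinned-ridge solutions)
to much tighter tolerances than a function-value-based stop can deliver.
A ratio optimized onto the lower bound is reported as a singular block;
fits whose mixed-model equations cannot be factorized raise a typed
error rather than silently changing the model.

Coefficients (fixed-effect BLUEs and random/penalized BLUPs) and their
unscaled covariance come from the Henderson equations at the optimum;
`vcov_unscaled = C^{-1}` so that contrasts on penalized coefficients are
as routine as contrasts on fixed ones.

### Degrees of freedom

The residual degrees of freedom of a mixed, weighted, shrunken fit are
not `n - p`.  The package uses the hat-matrix trace:

    df_res = sum(w_i) - trace(H),   trace(H) = (p + q) - trace(C^{-1} diag(pen))

which interpolates correctly between the limits (an unshrunk block
behaves like fixed columns; a block shrunk to zero contributes nothing)
and reduces exactly to `n - p` for plain regression.  This is a declared
modeling choice -- alternatives such as Satterthwaite approximations are
deliberately out of scope.

### Moderation and testing

Residual variances are moderated across proteins with the standard
empirical-Bayes squeeze: a scaled inverse chi-square prior `(d0, s0^2)`
is recovered by moment matching on `log s^2` (digamma/trigamma
relations; a non-positive excess dispersion yields `d0 = inf`), and each
protein's posterior variance is `(d0 s0^2 + df s^2) / (d0 + df)`.
Contrasts `L' theta` are tested with moderated Wald t statistics on
`df_res + d0` degrees of freedom (capped at 1e6, effectively normal, for
infinite `d0`).  Benjamini-Hochberg adjustment is applied within each
contrast across successfully fitted proteins; failed proteins are
excluded from the multiplicity count.  If every supplied variance is
identical the moment equations are degenerate and the prior is pooled at
the common value.

## Preprocessing and summarization

The default pipeline is: log2 transform, channel-median centering
(per sample column; a pooled per-channel variant exists), and -- for the
protein-level workflows -- Tukey median polish of each protein's
PSM x channel matrix within each run.  The polish sweeps row medians
first, then column medians, accumulating the effect-vector medians into
the overall term; the protein profile is `overall + column effects`.
Only fitted values and effect differences are contractual; the split of
level between the overall and effect vectors is convention.  The
convergence test compares successive residual L1 norms against
`tol (1 + residual L1)` -- a residual-based scale keeps the polish
exactly location-equivariant.  Even-count medians average the two
central values.  Non-convergence (possible oscillation under missing
data) is flagged, not raised.  The mixture-scoped variant stacks all
technical-repeat runs of a mixture as extra rows over the shared
channels, giving one value per biological replicate.

A one-step median sweep summarizer (row-center each PSM by its median,
then per-channel medians per protein, optionally column-centered) is
provided as the lighter alternative some published workflows use.

Spike-in benchmark data need three additional filters, all implemented
and reported: removal of spectra with identical intensity vectors mapped
to different proteins (ambiguous cross-database matches), a minimum
observed-value count per PSM (six of ten in the emulated study), and
resolution of duplicate spectra per peptide ion by maximal summed
intensity.  For designs where most proteins are truly changing, the
stable-background normalization is available: background PSMs correlated
with the spike-in profile (Pearson r > 0.25, pairwise-complete; fewer
than three pairs or zero variance counts as no evidence, hence kept) are
excluded, low signal-to-noise PSMs (summed SNR < 20) are dropped, and
samples are divided by the geometric mean of the 50% most stable
background PSMs per run (ties at the SD cutoff broken lexicographically
for determinism).

Missing intensities are `NaN` throughout; zero reporter intensities are
treated as missing on input by default (they are non-physical).  No
imputation is performed anywhere by default -- inference relies on
missingness being random given the peptide baseline -- but a hook
accepts a user-supplied assay-to-assay imputation function.

## Workflows

- `protein_rrilmm` -- summarize per run, then per protein: ridge on
  condition, random intercepts for run (plus mixture when runs are
  technical repeats), Huber robustness.
- `protein_rrilmm_mixture` -- summarize per mixture; mixture random
  intercept.
- `psm_rrilmm` -- model PSM intensities directly with random intercepts
  for sample, psm, and run.  Proteins whose model is unidentifiable --
  notably one-hit wonders (a single spectrum per run), where the sample
  and psm terms collapse into the residual or alias the run term -- are
  reported as fit failures.  No silent model switching: mixing different
  models across proteins without saying so hurts interpretability.
- `psm_rrilmm_refit` -- identical, but failed proteins are refitted under
  the largest identifiable sub-model (dropping psm first, then sample,
  then any aliased or single-level factor) and flagged `reduced`.

Robustness and ridge are independent switches, so the
lmm / rlmm / rilmm / rrilmm ablation grid is configuration, not code.
Dataset-wide degeneracies (e.g. a single run) drop the affected random
terms once, with a logged note.  Workflows are pure functions of their
inputs; reruns are byte-identical.

## Simulator

The generator mirrors the emulated benchmark layout: by default five
mixtures of ten channels, two reference channels carrying the
condition-average profile, and four conditions with two channels each.
Per protein it draws a PSM count from a zero-truncated Poisson (mean
parameter 2.5, so one-hit wonders occur with realistic probability --
about a fifth of proteins), a Gaussian protein baseline (mean 16, SD 2
on log2 scale) and peptide offsets (SD 1), and adds independent Gaussian
run (SD 0.3), mixture (SD 0.15), sample (SD 0.2), spectrum (SD 0.4) and
residual (SD 0.25) effects.  DA proteins spread their assigned log2 fold
change (grid 0.5 / 1 / 2 by default) linearly across the conditions,
emulating a dilution series; the published studies give no numeric
variance components, so these defaults are plausible values chosen to
make simulated operating characteristics qualitatively resemble reported
ones -- a calibration, not ground truth.  Missingness is missing-at-random
given the PSM baseline via a logistic model (low-abundance biased; a
missing-completely-at-random switch exists), with a deterministic
quadrature helper to set the intercept for a target marginal rate.
Outliers are additive log2 shifts of random sign.  Identical designs and
seeds give bit-identical data.

What the simulator does *not* emulate: reporter-ion interference and
ratio compression from cofragmentation (so simulated fold changes are
attenuation-free, unlike real TMT data where spike-in fold changes are
systematically underestimated), correlated missingness within spectra,
retention-time structure, and identification errors.  Passing tests on
simulated data therefore validate the statistical machinery under its
own assumptions, not robustness to those instrument-level artifacts.

## Validation and problem sizes

The test suite checks the machinery against independent oracles: an
independently coded median-polish iteration, closed-form balanced
one-way ANOVA REML estimators (including the boundary-truncated case),
the explicit ridge solution with a pinned penalty, ordinary least
squares, the pooled two-sample t statistic, a brute-force BH step-up,
and prior-recovery simulations.  End-to-end checks run the full
workflows on simulated data: null calibration uses 20 simulations of
2000 background-only proteins (mean observed FDP at the 5% BH threshold
below 0.07, null p-values uniform by KS); the contamination comparison
uses 20 simulations of 200 proteins with 10% outlier cells of 5 log2
units (robust ridge matches or beats the vanilla mixed model's TPR at
FDP <= 0.05 in at least 16); the refit check uses 150 proteins with 30%
one-hit wonders.  `scripts/acceptance.py` re-runs a scaled version of
these pipelines (500-protein spike-in benchmark, five 800-protein null
simulations) and writes the measured quantities as JSON; the sizes are
chosen so the whole script completes in a few minutes on one core while
keeping Monte-Carlo error well inside the tolerances quoted above.

## Known limitations

- Random-effect blocks are independent (diagonal `D`); crossed or
  correlated covariance structures are out of scope.
- Single-row (t-type) contrasts only; no multi-row F-tests.
- The effective-df definition is a pragmatic choice; p-values for very
  small, heavily shrunken fits should be read qualitatively.
- Channel-median normalization assumes most proteins are not changing;
  with many same-direction spike-ins it biases null fold changes away
  from zero (visible in DA-heavy simulations), which is a property of
  the normalization, not of the estimator -- the stable-background
  normalization exists for exactly that situation.
- The IRLS robustness loop reuses REML within each iteration; its
  weights are not propagated into the empirical-Bayes moment matching
  beyond the effective df.
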