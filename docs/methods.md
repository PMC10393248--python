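# Methods

This note documents the models and numerical choices behind
`tensoreeg`, what the synthetic-data generators do and do not emulate,
and the design decisions taken where the methodology is genuinely open.

## Sub-band decomposition

Channels are decomposed with a Daubechies-4 discrete wavelet transform
and the per-level *details* are reconstructed as band series. The dyadic
interval of detail level j is (fs/2^(j+1), fs/2^j); the level for each
named band is j = round(log2(fs / f_hi)) with f_hi the canonical upper
edge, which at 500 Hz gives D7→delta (≈2.0–3.9 Hz), D6→theta, D5→alpha,
D4→beta, D3→gamma, D2→gamma+ (62.5–125 Hz). D1 (>125 Hz) and the
level-7 approximation are collected into a residual. The transform uses
**periodization** boundary handling: the periodized orthogonal DWT gives
exact perfect reconstruction and exact energy additivity across bands
(details reconstructed from symmetric extension are only approximately
orthogonal at the edges, which would break the energy bookkeeping
identity we test at 1e-6 relative). Wavelet name, band map and depth are
configurable.

## Nonlinear measures

Per (channel, band) series, 12 measures. Definitions and defaults:

- **SampE** — sample entropy, m = 2, r = 0.2·SD, Chebyshev distance,
  ≤ r matching, self-matches excluded; both template counts use the
  N − m templates that admit an (m+1)-point continuation. A constant
  series gives 0 (r = 0, all templates match); "no (m+1)-matches" gives
  +inf and "no m-matches" gives NaN, both propagated, never silently
  replaced.
- **CD** — Grassberger–Procaccia correlation dimension, embedding
  dimension 10, delay 1. The correlation sum is evaluated on log-spaced
  radii between the 0.5% and 50% quantiles of the pairwise distance
  distribution and the slope is fitted on the contiguous half-window of
  radii with the most stable local slope (minimal slope SD). Constant
  series are a hard error.
- **DFA** — order-1 detrended fluctuation analysis, non-overlapping
  windows, box sizes log-spaced in [4, N/4], exponent from a global
  least-squares fit. White noise ⇒ α ≈ 0.5, Brownian motion ⇒ α ≈ 1.5
  (both covered by tests).
- **Recurrence measures** — time-delay embedding (m = 10, τ = 1,
  Euclidean norm), threshold set to the quantile of the off-diagonal
  pairwise distances matching the target recurrence rate 0.05 (attained
  rate therefore within ties of the target; asserted within ±0.005).
  Diagonal-line measures (DET, Lentr, Lmax, Lmean) exclude the line of
  identity (Theiler half-width 1) and use lmin = 2; both triangles of
  the symmetric plot are scanned, as is conventional. Vertical-line
  measures (LAM, TT, VertEnt) scan full columns including the LOI cell
  with vmin = 2 — this is what makes a saturated plot perfectly laminar
  (LAM = 1). AvgVertWhiteLen is the mean length of vertical runs of
  non-recurrent points. Empty line distributions yield 0 by convention.
  Note that a saturated N×N plot has DET = (N(N−1)−2)/(N(N−1)), not
  exactly 1: the two corner diagonals have length 1 and the standard
  denominator keeps them.
- τ = 1 everywhere for determinism and cross-band comparability; the
  delay, norm, Theiler width and line minima are configurable through
  `EmbeddingConfig`.

**Series length cap.** Embedding-based measures (SampE, CD, recurrence)
analyse at most `max_points` embedded points (default 2000), taken as a
prefix — truncation, not decimation, because resampling would destroy
diagonal line structure. Distance matrices are O(N²), so this bounds
both memory and time; DFA uses the full series. The end-to-end tests
and the acceptance script run at `max_points = 600` with 6-s, 8-channel
synthetic recordings, a deliberate problem-size choice that preserves
every qualitative property being tested while keeping the whole suite
desk-scale; the generator defaults themselves remain the study
conditions (19 channels, 30 s at 500 Hz).

Degenerate sub-signals (constant, too short) are recorded as missing
with a reason and the tensor builder's complete-case rule then excludes
the participant — values are never fabricated.

## Tensor assembly and supervision

The long feature table is pivoted into participant × measure × channel ×
band, plus a trailing age mode when several recording ages are required.
Complete case: a participant missing any required age or any cell is
dropped (no imputation). Cells are z-scored across participants; during
cross-validation the constants come from the training fold only, so no
held-out information leaks into the standardization. Supervision columns:
a 0/1 class contrast, then covariates — integer recording-age code
(1 = infancy, 3, 5, 7 years), sex assigned at birth (0/1), birthweight
in grams, exact initial-recording age in months. Named configurations
`eeg_only` / `eeg_sex` / `eeg_bw_sex` mirror the covariate sets used in
the evaluation design.

Whether features should be standardized before factorization is not
settled methodology; z-scoring is the package's choice (it stops
high-variance cells from dominating the Gaussian likelihood) and can be
disabled.

## SupCP estimation

The supervised CP model (rank R, diagonal score covariance Σ_f,
isotropic noise σ²) is fitted by EM on the matricized data. The E-step
needs only R×R solves: with W the Khatri–Rao product of the mode
loadings, W'W is the Hadamard product of the per-mode Gram matrices and
the conditional score covariance is (W'W/σ² + Σ_f⁻¹)⁻¹. M-step updates
of the loadings, B, Σ_f and σ² are closed-form conditional maximizers,
so the marginal log-likelihood is non-decreasing (asserted within 1e-8
relative in tests). The likelihood itself and the per-participant
marginal log-likelihood use the Woodbury identity; a dense
mean-and-covariance Gaussian oracle verifies them on small models.

Choices left open by the methodology, resolved as follows: random
orthonormal initialization of the loadings (seeded), B = 0, σ² = half
the data variance; convergence at relative log-likelihood change < 1e-6
or 500 iterations; scale indeterminacy resolved by unit-norm loading
columns with magnitudes absorbed into B and Σ_f (likelihood-invariant);
Σ_f diagonal (not isotropic), floored at 1e-12. EM on CP structure can
stall in local optima, so `fit_supcp(..., n_starts=k)` runs k seeded
starts and keeps the best final log-likelihood; recovery-style analyses
use 3–5 starts. Rank defaults to 30, the working rank of the original
analysis; small synthetic studies in the tests use smaller ranks matched
to their mode dimensions.

## Classification and evaluation

For a held-out participant, each candidate class is substituted into the
class column of y_i (observed covariates kept), the marginal
log-likelihood is computed under the training-fold model, and Bayes'
rule with training-fold class proportions (configurable to uniform)
gives posteriors; the argmax is the prediction, ties breaking toward the
first class. Stratified k-fold cross-validation (k = 5, shrinking to the
minority-class size when smaller) refits SupCP per fold. AUROC uses the
pooled held-out positive-class posteriors (per-fold averaging available
but pooling is the primary estimate, since tiny folds make per-fold
AUROC degenerate); the Brier score is the mean squared probability
error. Age regression takes factors with |r| > 0.2 against age and
reports cross-validated r, r², and MAE for a fixed suite of standard
regressors (k-NN, linear, random forest, gradient boosting, RBF and
linear SVR).

## Synthetic data

**Tensor generator** draws directly from the SupCP generative model
(scores U = YB + F, unit-norm random loadings, entrywise Gaussian
noise), with the supervision matrix built by the same encoding path as
the real tensor builder, so recovery tests exercise the production code.
Noiseless draws are exactly rank-R (verified via multilinear singular
values).

**EEG cohort generator.** Each channel mixes (a) per-band filtered
Gaussian noise and (b) a recording-wide smooth deterministic component
(alpha-range sinusoid plus a logistic-map orbit stepped at fs/16 and
interpolated). Each band's noise is itself a mixture of a bottom-edge
(smooth) and a full-band (rough) component; the mixing weight

    c = 0.5 + 0.6·age_effect·((age−1)/6 − 0.5) − 0.3·group_effect·sign(group)

is the *within-band roughness* dial, clipped to [0.05, 0.95], with
sign +1 for the anxiety-like group, −1 for the externalizing-like group
and 0 for controls. This dial was chosen empirically: wavelet detail
series are heavily oversampled and spectrally shaped by the wavelet
filter itself, so the nonlinear measures are nearly blind to additive
narrowband components, global spectral tilt, or broadband additive
chaos — but they respond strongly and consistently to how energy is
distributed *within* each dyadic band (roughness up ⇒ sample entropy up,
determinism and DFA down in every band). Raising roughness with age
emulates developmental complexification; shifting it oppositely for the
two disorder groups makes a merged "atypical" class heterogeneous, which
reproduces the qualitative finding that the merged contrast classifies
worse than either pairwise contrast.

Effect sizes are free parameters (no published estimates exist for
these measures in this design); the defaults (age_effect = 1,
group_effect = 0.5) were fixed once as a clearly detectable regime, with
0 giving exact nulls. What passing tests show: the *pipeline* recovers
planted structure and discriminates groups whose sub-band dynamics
differ. What they do not show: that real anxious and healthy children
differ this way, or by this much — the generator has no volume
conduction, no artifacts, no inter-channel covariance structure beyond
the shared oscillation, and no physiological band powers.

Null-generator caveat: with both effects at 0 the recordings are i.i.d.
across participants, so the age–SampEn correlation at n = 50 is a pure
null statistic with SD ≈ 0.15; the |r| < 0.2 check is a fixed-seed
regression guard, not a distributional guarantee.

## Cohort grouping

Lifetime-diagnosis rules: anxiety = any of {GAD, SAD, SP} and no
externalizing diagnosis; externalizing = any of {ADHD, ODD, CD} and no
anxiety diagnosis; healthy control = no diagnosis at all; anything else
(cross-family comorbidity, or only diagnoses outside both families,
e.g. PTSD alone) is excluded with a recorded reason. Mood/other
diagnoses comorbid with exactly one family leave the assignment
unchanged (MDD + ADHD stays externalizing). Summary percentages are
rounded to the nearest integer, matching the convention of the published
summary table they are checked against.

## Known limitations

- Recurrence measures at τ = 1 on heavily oversampled band series sit
  near their saturation values (DET ≳ 0.92); group differences are
  small per cell and the pipeline's power comes from pooling hundreds of
  cells in the factorization.
- The EDF writer is minimal (16-bit, 1-s records, integer sampling
  rates, one physical range per channel); it is sufficient for
  round-tripping analysis segments, not a general-purpose EDF+ library.
- Age enters the latent model as a discrete mode/covariate; continuous
  age trajectories are out of scope.
- The age-validation protocol fits the factorization on the full sample
  (supervised by age) before cross-validating the regressors, mirroring
  the original design; on clean synthetic gradients this yields
  near-perfect r, and it should be read as a validity check of the
  factorization, not an unbiased estimate of predictive accuracy.
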