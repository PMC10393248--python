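# tensoreeg

Nonlinear EEG dynamics and supervised tensor factorization for
developmental biomarker discovery.

## The problem

Resting-state EEG carries information about how a child's brain dynamics
mature and how they differ in emerging psychopathology (anxiety,
externalizing disorders). A single recording yields a very large set of
candidate features: nonlinear dynamical measures, computed per electrode
and per frequency band, at repeated recording ages. Screening hundreds of
correlated values one at a time is inefficient and ignores their joint
structure. `tensoreeg` implements the alternative: organize the measures
into a multiway array and extract a small number of *supervised latent
factors* that are simultaneously patterns over measures, electrodes,
bands and ages, and that are informed by diagnostic labels and clinical
covariates.

The package is aimed at computational-psychiatry and EEG-methods
researchers who want a tested, reusable implementation of this pipeline
and a synthetic-data harness to validate it, since clinical EEG cohorts
generally cannot be shared.

## The model

Each channel is split into six sub-band series with a Daubechies-4
discrete wavelet transform (details D7..D2 at 500 Hz ≈ delta, theta,
alpha, beta, gamma, gamma+). From every (channel, band) series, 12
nonlinear measures are computed: sample entropy (SampE), correlation
dimension (CD), the DFA scaling exponent, seven recurrence-plot measures
(RR, DET, LAM, TT, Lentr, Lmax, Lmean; fixed recurrence rate 0.05,
embedding dimension 10) and two vertical-line recurrence measures
(VertEnt, AvgVertWhiteLen). The values form a tensor

    X : participants × 12 measures × 19 channels × 6 bands [× ages]

which is factorized with the supervised canonical polyadic (SupCP) model

    X_i = Σ_r u_ir (v¹_r ∘ v²_r ∘ … ) + E_i,   u_i = y_i B + f_i,
    f_i ~ N(0, Σ_f),   E_i ~ N(0, σ²I),

fitted by EM. Marginalizing the scores u_i gives a Gaussian likelihood
per participant; substituting each candidate class into y_i and applying
Bayes' rule yields posterior class probabilities. Generalizability is
assessed with stratified k-fold cross-validation (SupCP refitted per
training fold), scored by pooled AUROC and Brier score; latent factors
correlated with age (|r| > 0.2) feed a standard regression suite for the
age-prediction validity check.

## Worked example

```python
import numpy as np
from tensoreeg import (CohortSimSpec, simulate_eeg_cohort,
                       FeatureConfig, build_tensor, crossval_classify)
from tensoreeg.features import cohort_feature_table

spec = CohortSimSpec(group_sizes={"healthy_control": 20, "anxiety": 20},
                     n_channels=8, duration=6.0, group_effect=1.0,
                     age_effect=0.0, seed=2)
recordings, participants = simulate_eeg_cohort(spec)
features = cohort_feature_table(recordings, FeatureConfig(max_points=600))
tensor, supervision = build_tensor(
    features, participant_table=participants,
    contrast=("anxiety", "healthy_control"), standardize=False)
result = crossval_classify(tensor, supervision, rank=10, k=5, seed=0)
print(f"AUROC {result.auroc:.3f}  Brier {result.brier:.3f}")
```

Output:

```
AUROC 0.997  Brier 0.037
```

The synthetic anxiety group's sub-band dynamics are more regular than
the controls' (the generator's `group_effect` dial); the cross-validated
posterior probabilities separate the groups almost perfectly, so the
AUROC is near 1 and the Brier score (mean squared probability error) is
near 0. Permuting the labels collapses the AUROC to ≈ 0.5.

A command-line interface mirrors the library
(`tensoreeg simulate-cohort / extract-features / build-tensor /
fit-supcp / crossval`).

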