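# Methods

## Model

`mciprog` implements a prototype-based prognostic model for MCI-to-AD
progression.  A binary GMLVQ classifier represents each class by one
prototype and measures distance with a learned full quadratic metric
`d(x, w) = (x − w)ᵀ Λ (x − w)` with `Λ = ΩᵀΩ / tr(ΩᵀΩ)`.  Training
minimizes the GLVQ cost `Σᵢ φ(μᵢ)` with the relative margin
`μ = (d_J − d_K)/(d_J + d_K)` and the identity link `φ(μ) = μ`.  The
identity link was chosen over a sigmoid so that the only tuned
hyper-parameters are the two learning rates; a sigmoid steepness would add
a third knob without changing the decision geometry.

Gradients are analytic: per sample, `∂μ/∂d_J = 2 d_K/(d_J + d_K)²`,
`∂μ/∂d_K = −2 d_J/(d_J + d_K)²`, `∂d/∂w = −2 (ΩᵀΩ)(x − w)` and
`∂d/∂Ω = 2 Ω (x − w)(x − w)ᵀ`, chain-ruled and summed.  A central
finite-difference implementation of the same gradient exists purely as a
test oracle and agrees with the analytic forms to better than 1e-5 relative
error across random instances.

### Optimization and numerical choices

* Full-batch gradient descent with fixed learning rates, no momentum, no
  shuffling: determinism and testability take priority over convergence
  speed at these tiny dimensionalities (p = 3).
* Learning rates are *per-sample*: the summed-cost gradient is divided by n
  before the step, so defaults transfer across cohort sizes.  Defaults
  `alpha_w = 0.1`, `alpha_omega = 0.05`, 300 epochs — on standardized
  features these converge on all simulated regimes exercised by the tests.
* Prototypes initialize at class-conditional means plus optional seeded
  Gaussian jitter (`jitter_sd`, default 0); Ω initializes to `I/√p` so the
  metric starts at the uniform `Λ = I/p`.
* After every Ω update, Ω is rescaled by `1/√tr(ΩᵀΩ)`.  Rescaling Ω (rather
  than projecting Λ) preserves positive semidefiniteness exactly, and
  leaves the cost unchanged because μ is scale-invariant in the metric.
* Margins inside training use the pre-normalization metric ΩᵀΩ; reported
  distances use the unit-trace Λ.  The two differ only by a positive scalar,
  so classifications and margins are identical.
* The cost trace stores the cost entering each epoch plus one final
  post-update value (epochs + 1 entries).
* Exact prediction ties (|d_s − d_p| < 1e-12) resolve to the progressive
  class, favoring sensitivity — the clinically conservative direction.
* Degenerate inputs raise typed errors rather than returning NaN: zero Ω,
  coincident prototypes, zero-variance features, single-class labels.

## Ensemble under class imbalance

Memory-clinic cohorts are imbalanced (the reference configuration is 290
stable / 120 progressive).  The ensemble draws `n_resamples = 400` balanced
resamples — every minority subject plus an equal-count majority subset
sampled without replacement — and trains one member per resample with seed
`base_seed + i`, making members reproducible and order-independent.

Members are ranked by balanced accuracy **on the full training sample**,
not their own resample: resample accuracy is optimistically biased and
discriminates poorly among members.  The top `selection_fraction = 0.20`
(80 of 400) are retained; ranking ties break by lower final cost, then
lower member index, so selection is deterministic.  Prediction is majority
vote among selected members; an exact vote tie falls back to the averaged
model's distances, then to the progressive class.  The continuous ensemble
score is the mean member margin `(d_s − d_p)/(d_s + d_p)` and feeds the
AUC.  Averaged prototypes and the averaged relevance matrix are arithmetic
means over the selected members only; a mean of unit-trace matrices has
unit trace, so no renormalization is applied or needed.

## Prognostic index and stratification

The raw index is the metric scalar projection onto the averaged prototype
axis, `s(x) = (x − w̄_s)ᵀ Λ̄ (w̄_p − w̄_s) / (w̄_p − w̄_s)ᵀ Λ̄ (w̄_p − w̄_s)`
— the unique affine map that is 0 at the stable prototype and 1 at the
progressive prototype and measures displacement along the disease axis in
the learned metric.  Strata: stable below 0, slowly progressive from 0 to 1
inclusive (a closed middle interval, chosen for determinism), rapidly
progressive above 1.

By default calibration is the identity (`prototype_anchor`).  With
longitudinal decline rates available, boundaries can be re-fit: subjects
are split into quartile classes by decline rate (MMSE points lost per year,
positive = decline), a multinomial logistic model of quartile class on the
raw index is fitted (near-unregularized, C = 1e6), and the boundaries move
to the index values where the most-probable class leaves the bottom
quartile (→ 0) and enters the top quartile (→ 1).  Crossings are located by
bisection on the fitted class scores; a non-monotone or non-spanning
most-probable-class sequence raises a calibration error, with the anchor
calibration as the documented fallback.  On a finite sample the fitted
boundary sits in the gap between adjacent quartile samples, so it matches
the decline-percentile index values only up to the local inter-sample
spacing — the tolerance the tests use.

## Covariate adjustment and preprocessing

Features are adjusted by OLS of each feature on age, sex (0/1) and years of
education, fit on the training subset only: `x_adj = x − ĉᵀ(z − z̄_fit)`.
Subtracting only the covariate *deviation* effect keeps adjusted features
on their clinical scales.  Features are then z-scored with training-subset
moments.  Both models are applied unchanged to held-out data; the
evaluation protocol re-fits them inside every cross-validation fold
(leakage guard, asserted by tests that corrupt non-subset rows).

## Evaluation protocol

Repeated stratified k-fold cross-validation, default 10 folds × 10
iterations.  Sensitivity, specificity and balanced accuracy (progressive
MCI positive) aggregate fold confusion counts within each iteration; AUC
uses the Mann–Whitney midrank convention on pooled iteration scores.  The
report carries per-fold counts, per-iteration metrics, pooled metrics, and
t-based 95% confidence half-widths across iterations.  Nested tuning runs
an inner 5-fold cross-validation per outer training fold over candidate
learning-rate pairs, scoring by mean balanced accuracy; ties prefer smaller
rates, then grid order, and the modal per-outer-fold winner is returned.

## Synthetic cohorts

The generator emulates the statistical structure the model assumes:

* Classes of sizes 290/120 by default.  A continuous latent progression
  signal `g ~ N(class indicator, τ²)`, τ = 0.6, with class means exactly 0
  (stable) and 1 (progressive); the within-class spread reflects clinical
  heterogeneity of the MCI label and is what makes a *continuous* index
  informative beyond the binary labels.
* Features on clinical scales: noise-free mean `stable_mean + g·Δ·sd` with
  standardized class separation Δ = (−1.0, −0.7, −0.6) for ACE-R memory,
  MMSE and GM density (memory most discriminative), plus exchangeably
  correlated Gaussian noise (ρ = 0.3) and linear covariate effects.
  Covariates: age ~ N(73, 7²) yr, sex ~ Bernoulli(0.5), education ~
  N(16, 3²) yr.
* Outcomes: decline rate `0.5 + 2.0·g + N(0, 1)` MMSE points lost per year;
  conversion time exponential with hazard `0.08·exp(1.2·g)` per year,
  censored at a 6-year horizon.
* Ground truth (`g`, class) lives in a separate truth table the pipeline
  never sees.

What the generator does **not** emulate: real research-cohort or
memory-clinic marginals,
floor/ceiling effects of bounded cognitive scales, scanner and site
effects, missing data, or non-Gaussian tails.  Passing tests therefore
demonstrate correctness of the machinery and recoverability of planted
structure, not clinical performance on real cohorts.

## Problem sizes used in tests and the acceptance script

Unit tests run on cohorts of 64–410 subjects with 4–25-member ensembles;
the reference 400-member configuration is exercised once (selection
arithmetic and metric normalization).  The discrimination checks use a
separable cohort with a 3-sd standardized gap on every feature (Mahalanobis
gap ≈ 4.1 sd, Bayes balanced accuracy ≈ 98%) and its label-permuted null.
Coupling and relevance-recovery checks aggregate over 10 seeds with
20-member ensembles.

One caveat worth stating: cross-validated accuracy under a label-permuted
null is known to fall slightly *below* chance in finite samples, because
resampling labels without replacement anticorrelates the train- and
test-fold label assignments.  At n = 400 the shift averages two to three
percentage points, and single permutation draws combine it with ±2-point
sampling noise, so individual null runs can land several points below 50%
without indicating leakage or a defect.

## Known limitations

* One prototype per class and a single global metric; no localized metrics
  or kernelized variants.
* Binary sMCI/pMCI training only; other labels pass through prediction but
  are excluded from fitting.
* The boundary-calibration construction (quartile classes on decline rate,
  transition points of the most-probable class) is one consistent reading
  of an under-determined design space; the anchor calibration is the
  default precisely because it is assumption-free.
* Survival validation of the strata (Cox models, Kaplan–Meier curves) is
  left to standard libraries on the prediction output; the package reports
  raw conversion-rate separation only.
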