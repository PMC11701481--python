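# mciprog

Interpretable prototype-based prognostic modelling of progression from mild
cognitive impairment (MCI) to Alzheimer's disease (AD).

## The problem

Patients presenting with MCI differ widely in outcome: many remain stable for
years, others progress to AD within a short window.  Routinely collected,
low-cost measures — two cognitive tests (the ACE-R memory subscale and the
MMSE) and a single structural-MRI summary (medial-temporal grey-matter
density) — carry prognostic signal, but a clinically usable model must be
interpretable, robust to the strong class imbalance of memory-clinic cohorts,
and able to express *how fast* an individual is likely to progress rather
than only a binary label.  `mciprog` is aimed at methodologists and applied
researchers who want such a model as a reproducible, testable library.

## The model

The core classifier is **Generalized Matrix Learning Vector Quantization
(GMLVQ)**.  Each diagnostic class (stable MCI `sMCI`, progressive MCI
`pMCI`) is represented by a prototype `w` in feature space, and distance is
measured with a learned full quadratic metric

    d(x, w) = (x − w)ᵀ Λ (x − w),   Λ = ΩᵀΩ / tr(ΩᵀΩ),

where Λ is symmetric, positive semidefinite and normalized to unit trace.
Its diagonal ranks per-feature relevance; off-diagonal terms expose pairwise
feature interactions.  Training minimizes the GLVQ cost, the sum over
samples of the relative margin

    μ = (d_J − d_K) / (d_J + d_K) ∈ [−1, 1],

(`d_J` = distance to the correct-class prototype, `d_K` = distance to the
other prototype) by full-batch gradient descent on the prototypes and Ω.

Around the classifier:

* **Balanced resampling ensemble** — the majority class is repeatedly
  (default 400×) down-sampled to the minority size; one GMLVQ model is
  trained per resample, members are ranked by balanced accuracy on the full
  training sample, the top 20% are kept, and predictions are made by
  majority vote.  The selected members' prototypes and relevance matrices
  are averaged.
* **Prognostic index** — the scalar projection of a subject onto the
  averaged prototype axis under the averaged metric,

      s(x) = (x − w̄_s)ᵀ Λ̄ (w̄_p − w̄_s) / (w̄_p − w̄_s)ᵀ Λ̄ (w̄_p − w̄_s),

  anchored at 0 for the stable prototype and 1 for the progressive one.
  Subjects are stratified as stable (index < 0), slowly progressive (0–1) or
  rapidly progressive (> 1); the 0/1 boundaries can optionally be
  re-calibrated against observed decline rates via multinomial logistic
  regression over decline-rate quartiles.
* **Evaluation** — repeated stratified k-fold cross-validation (default
  10 × 10) with all preprocessing (OLS covariate adjustment for age, sex and
  education; z-scoring) fit inside each training fold, plus nested
  cross-validation for tuning the two learning rates.
* **Synthetic cohorts** — a generator producing imbalanced two-class
  Gaussian cohorts with a continuous latent progression signal, covariate
  effects, decline rates and censored conversion times, used as ground
  truth by the entire test suite.

## Worked example

```python
import numpy as np
from mciprog import ProgressionModel, SimulationParams, simulate_baseline, simulate_cohort

train, _ = simulate_baseline(SimulationParams(seed=7))          # 290 sMCI / 120 pMCI
model = ProgressionModel(n_resamples=50, random_state=7).fit(train)
print(np.round(np.diag(model.ensemble_.averaged_lambda_), 3))   # [0.695 0.265 0.04 ]

val, _ = simulate_cohort(SimulationParams(n_stable=100, n_progressive=100, seed=507))
table = model.predict_cohort(val)
print(table.head(3).round(3))
```

```
subject_id  raw_index  calibrated_index             stratum majority_vote_label  ensemble_score
     S0000      0.732             0.732  slowly_progressive                pMCI           0.716
     S0001      0.620             0.620  slowly_progressive                pMCI           0.415
     S0002      0.632             0.632  slowly_progressive                pMCI           0.462
```

The relevance diagonal shows the memory score dominating the learned metric
(0.695 of the unit trace), as the generator's class separation intends.  On
the held-out cohort the index correlates with the simulated rate of MMSE
decline (Spearman ρ = 0.559), and the strata split 35 stable / 123 slowly
progressive / 42 rapidly progressive.

The same pipeline is available from the shell:

```sh
mciprog simulate --seed 7 --out cohort.csv --truth-out truth.csv
mciprog train cohort.csv --seed 7 --out model.json
mciprog predict model.json cohort.csv --out predictions.csv
mciprog evaluate cohort.csv --seed 7 --out report.json
mciprog tune cohort.csv --seed 7 --out best.json
```

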