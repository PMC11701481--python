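"""Synthetic MCI cohort generator.

Emulates the statistical structure the prognostic model assumes, providing
ground truth for every test in the repository:

* two diagnostic classes (stable vs progressive MCI, default sizes 290/120)
  whose baseline features (ACE-R memory, MMSE, grey-matter density) differ
  by a class-mean shift ``delta`` in standardized units, largest on the
  memory score;
* a continuous latent progression signal ``g`` with class means exactly
  0 (stable) and 1 (progressive) and within-class s.d. ``severity_sd``,
  reflecting clinical heterogeneity within the MCI label;
* exchangeably correlated Gaussian feature noise (correlation ``rho``);
* linear covariate effects (age, sex, education) added to the features, so
  covariate adjustment has something real to remove;
* longitudinal outcomes coupled to ``g``: a decline rate (MMSE points lost
  per year) ``beta0 + beta1 * g + noise`` and a conversion time drawn from
  an exponential with hazard ``lambda0 * exp(gamma * g)``, censored at the
  follow-up horizon.

The noise-free feature displacement of a subject is ``g * delta`` (in sd
units), so projecting it onto ``delta`` and rescaling to class means 0/1
recovers ``g`` exactly: ground truth is independent of the noise draw.  The
truth table (subject id, g, class) is returned separately so the pipeline
under test never sees it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    DEFAULT_COVARIATES,
    DEFAULT_FEATURES,
    PROGRESSIVE_LABEL,
    STABLE_LABEL,
    Cohort,
)

# stable-class feature means and within-class s.d. on clinical scales
_STABLE_MEANS = (18.0, 27.0, 0.45)  # ACE-R memory /26, MMSE /30, GM density
_FEATURE_SDS = (4.0, 2.0, 0.05)

# covariate effects on features, per (age yr, sex code, education yr),
# expressed on each feature's clinical scale
_COVARIATE_COEFS = (
    (-0.10, 0.3, 0.20),  # ace_r_memory
    (-0.05, 0.1, 0.10),  # mmse
    (-0.002, 0.004, 0.001),  # gm_density
)
_COVARIATE_MEANS = (73.0, 0.5, 16.0)


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the synthetic cohort.

    Defaults mirror the imbalanced research-cohort setting the model targets
    (290 stable / 120 progressive) with the memory score carrying the
    largest class separation.
    """

    n_stable: int = 290
    n_progressive: int = 120
    delta: tuple[float, ...] = (-1.0, -0.7, -0.6)  # sd units, progressive lower
    rho: float = 0.3
    severity_sd: float = 0.6
    age_mean: float = 73.0
    age_sd: float = 7.0
    education_mean: float = 16.0
    education_sd: float = 3.0
    beta0: float = 0.5  # decline intercept, MMSE points/yr
    beta1: float = 2.0  # decline per unit latent signal
    sigma_d: float = 1.0  # decline noise s.d.
    lambda0: float = 0.08  # baseline conversion hazard, 1/yr
    gamma: float = 1.2  # log-hazard slope in the latent signal
    horizon: float = 6.0  # follow-up horizon, years
    seed: int = 0
    feature_names: tuple[str, ...] = DEFAULT_FEATURES

    def __post_init__(self) -> None:
        if self.n_stable < 2 or self.n_progressive < 2:
            raise ValueError("each class needs at least 2 subjects")
        if len(self.delta) != len(self.feature_names):
            raise ValueError("delta length must match feature count")
        p = len(self.feature_names)
        if not -1.0 / (p - 1) < self.rho < 1.0:
            raise ValueError(f"rho={self.rho} gives a non-positive-definite correlation")
        if self.sigma_d < 0 or self.severity_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if self.lambda0 <= 0 or self.horizon <= 0:
            raise ValueError("lambda0 and horizon must be > 0")


def _correlation_cholesky(p: int, rho: float) -> np.ndarray:
    corr = np.full((p, p), rho)
    np.fill_diagonal(corr, 1.0)
    return np.linalg.cholesky(corr)


def simulate_baseline(params: SimulationParams) -> tuple[Cohort, pd.DataFrame]:
    """Draw a labeled baseline cohort and its ground-truth table.

    Returns ``(cohort, truth)`` where ``truth`` has columns ``subject_id``,
    ``g`` (latent progression signal) and ``class``.  Deterministic given
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_stable + params.n_progressive
    p = len(params.feature_names)
    labels = np.array(
        [STABLE_LABEL] * params.n_stable + [PROGRESSIVE_LABEL] * params.n_progressive
    )
    class_ind = (labels == PROGRESSIVE_LABEL).astype(float)

    g = class_ind + rng.normal(0.0, params.severity_sd, n)
    delta = np.asarray(params.delta, float)
    sds = np.asarray(_FEATURE_SDS[:p], float)
    means = np.asarray(_STABLE_MEANS[:p], float)

    noise = rng.standard_normal((n, p)) @ _correlation_cholesky(p, params.rho).T

    age = rng.normal(params.age_mean, params.age_sd, n)
    sex = rng.integers(0, 2, n).astype(float)
    education = rng.normal(params.education_mean, params.education_sd, n)
    Z = np.column_stack([age, sex, education])
    coefs = np.asarray(_COVARIATE_COEFS[:p], float)
    cov_effect = (Z - np.asarray(_COVARIATE_MEANS)) @ coefs.T

    X = means + (g[:, None] * delta + noise) * sds + cov_effect

    ids = np.array([f"S{i:04d}" for i in range(n)])
    df = pd.DataFrame({"subject_id": ids})
    for j, name in enumerate(params.feature_names):
        df[name] = X[:, j]
    df["age"], df["sex"], df["education"] = age, sex, education
    df["label"] = labels
    cohort = Cohort(df, params.feature_names, DEFAULT_COVARIATES)
    truth = pd.DataFrame({"subject_id": ids, "g": g, "class": labels})
    return cohort, truth


def simulate_longitudinal(
    cohort: Cohort, truth: pd.DataFrame, params: SimulationParams
) -> Cohort:
    """Fill decline-rate and conversion outcomes from the latent signal.

    Decline rate is ``beta0 + beta1 * g + N(0, sigma_d)`` (MMSE points lost
    per year).  Conversion time is exponential with rate
    ``lambda0 * exp(gamma * g)``; draws beyond the horizon are censored
    (``conversion_status`` False, ``conversion_time`` = horizon).  Uses a
    seed offset from ``params.seed`` so baseline draws are unaffected.
    """
    if list(truth["subject_id"].astype(str)) != list(cohort.subject_ids):
        raise ValueError("truth table is not aligned with the cohort")
    rng = np.random.default_rng(params.seed + 1_000_003)
    g = truth["g"].to_numpy(float)
    n = len(g)

    decline = params.beta0 + params.beta1 * g + rng.normal(0.0, params.sigma_d, n)
    rate = params.lambda0 * np.exp(params.gamma * g)
    t_conv = rng.exponential(1.0 / rate)
    converted = t_conv <= params.horizon
    time = np.where(converted, t_conv, params.horizon)

    df = cohort.data.copy()
    df["mmse_change_rate"] = decline
    df["cdr_change_rate"] = 0.25 * decline  # CDR worsens with the same signal
    df["conversion_status"] = converted
    df["conversion_time"] = time
    return cohort.replace_data(df)


def simulate_cohort(params: SimulationParams) -> tuple[Cohort, pd.DataFrame]:
    """Baseline + longitudinal outcomes in one call."""
    cohort, truth = simulate_baseline(params)
    return simulate_longitudinal(cohort, truth, params), truth
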