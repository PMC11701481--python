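"""End-to-end prognostic model: adjustment → standardization → ensemble → index.

:class:`ProgressionModel` chains the preprocessing (covariate adjustment and
feature standardization, both fit on the training cohort only), the balanced
GMLVQ ensemble, and the scalar-projection prognostic index with optional
decline-rate boundary calibration.  It is the object the command-line
``train``/``predict`` commands serialize, and the unit that cross-validation
fits per fold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import (
    Cohort,
    CovariateAdjuster,
    FeatureStandardizer,
    PROGRESSIVE_LABEL,
)
from .ensemble import BalancedGmlvqEnsemble, ResamplePlan
from .exceptions import CalibrationError, SchemaError
from .prognosis import (
    PROTOTYPE_ANCHOR,
    BoundaryCalibration,
    apply_calibration,
    calibrate_boundaries,
    scalar_projection,
    stratify,
)


class ProgressionModel(BaseEstimator):
    """Covariate-adjusted GMLVQ ensemble with a prognostic index.

    Parameters
    ----------
    n_resamples, selection_fraction, alpha_w, alpha_omega, epochs, jitter_sd:
        Passed to :class:`BalancedGmlvqEnsemble`.
    calibration:
        ``"prototype_anchor"`` (identity: 0 at the stable prototype, 1 at the
        progressive prototype) or ``"multinomial_logistic"`` (requires
        ``mmse_change_rate`` outcomes on the training cohort).
    random_state:
        Master seed; the resample plan and member seeds derive from it.

    Fitted attributes: ``adjuster_``, ``standardizer_``, ``ensemble_``,
    ``calibration_``, ``feature_names_``.
    """

    def __init__(
        self,
        n_resamples: int = 400,
        selection_fraction: float = 0.20,
        alpha_w: float = 0.1,
        alpha_omega: float = 0.05,
        epochs: int = 300,
        jitter_sd: float = 0.0,
        calibration: str = "prototype_anchor",
        random_state: int = 0,
    ):
        self.n_resamples = n_resamples
        self.selection_fraction = selection_fraction
        self.alpha_w = alpha_w
        self.alpha_omega = alpha_omega
        self.epochs = epochs
        self.jitter_sd = jitter_sd
        self.calibration = calibration
        self.random_state = random_state

    def fit(self, cohort: Cohort, plan: ResamplePlan | None = None) -> "ProgressionModel":
        train = cohort.labeled_subset()
        self.feature_names_ = list(train.feature_names)
        self.adjuster_ = CovariateAdjuster().fit(train)
        adjusted = self.adjuster_.transform(train)
        self.standardizer_ = FeatureStandardizer().fit(adjusted)
        standardized = self.standardizer_.transform(adjusted)

        self.ensemble_ = BalancedGmlvqEnsemble(
            n_resamples=self.n_resamples,
            selection_fraction=self.selection_fraction,
            alpha_w=self.alpha_w,
            alpha_omega=self.alpha_omega,
            epochs=self.epochs,
            jitter_sd=self.jitter_sd,
            random_state=self.random_state,
        ).fit(standardized.features(), standardized.labels, plan=plan)

        if self.calibration == "multinomial_logistic":
            if "mmse_change_rate" not in train.data.columns:
                raise CalibrationError(
                    "multinomial_logistic calibration needs mmse_change_rate outcomes"
                )
            raw = self.raw_index(train)
            self.calibration_: BoundaryCalibration = calibrate_boundaries(
                raw, train.data["mmse_change_rate"].to_numpy(float)
            )
        else:
            self.calibration_ = PROTOTYPE_ANCHOR
        return self

    # -- transforms ----------------------------------------------------------------

    def _preprocess(self, cohort: Cohort) -> np.ndarray:
        if cohort.feature_names != self.feature_names_:
            raise SchemaError(
                f"cohort features {cohort.feature_names} do not match "
                f"model features {self.feature_names_}"
            )
        return self.standardizer_.transform(self.adjuster_.transform(cohort)).features()

    def raw_index(self, cohort: Cohort) -> np.ndarray:
        """Raw scalar-projection prognostic index for every subject."""
        X = self._preprocess(cohort)
        w_s, w_p = self.ensemble_.averaged_prototypes_
        return np.asarray(
            scalar_projection(w_s, w_p, self.ensemble_.averaged_lambda_, X)
        )

    def predict_cohort(self, cohort: Cohort) -> pd.DataFrame:
        """Per-subject predictions: vote, score, raw/calibrated index, stratum."""
        X = self._preprocess(cohort)
        raw = self.raw_index(cohort)
        calibrated = np.asarray(apply_calibration(raw, self.calibration_))
        return pd.DataFrame(
            {
                "subject_id": cohort.subject_ids,
                "raw_index": raw,
                "calibrated_index": calibrated,
                "stratum": [stratify(t) for t in calibrated],
                "majority_vote_label": self.ensemble_.predict(X).astype(str),
                "ensemble_score": self.ensemble_.decision_function(X),
            }
        )

    def predict(self, cohort: Cohort) -> np.ndarray:
        """Majority-vote class labels."""
        return self.ensemble_.predict(self._preprocess(cohort))

    def decision_function(self, cohort: Cohort) -> np.ndarray:
        """Continuous ensemble score (positive → progressive)."""
        return self.ensemble_.decision_function(self._preprocess(cohort))

    @property
    def positive_label(self) -> str:
        return PROGRESSIVE_LABEL
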