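"""Cohort container, CSV I/O, covariate adjustment and feature standardization.

A cohort is a table with one row per subject: three baseline features
(ACE-R memory subscale, MMSE, medial-temporal grey-matter density),
confounding covariates (age, sex, years of education), a diagnostic label
(stable MCI ``sMCI``, progressive MCI ``pMCI``, ``other``, or ``unlabeled``)
and optional longitudinal outcomes (rate of MMSE decline, rate of CDR change,
conversion to AD status and time).

Features are adjusted for covariates by subtracting the covariate *deviation*
effect estimated by ordinary least squares on a designated fitting subset:
``x_adj = x - c^T (z - z_bar_fit)``.  Subtracting only the deviation keeps
adjusted features on their original, clinically interpretable scales.
Adjustment and standardization models are fit on training data only and
applied unchanged to held-out data (leakage guard).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import (
    AdjustmentError,
    CohortValidationError,
    DegeneracyError,
    ParseError,
    SchemaError,
)

DEFAULT_FEATURES: tuple[str, ...] = ("ace_r_memory", "mmse", "gm_density")
DEFAULT_COVARIATES: tuple[str, ...] = ("age", "sex", "education")
OUTCOME_COLUMNS: tuple[str, ...] = (
    "mmse_change_rate",
    "cdr_change_rate",
    "conversion_status",
    "conversion_time",
)
VALID_LABELS: frozenset[str] = frozenset({"sMCI", "pMCI", "other", "unlabeled"})

STABLE_LABEL = "sMCI"
PROGRESSIVE_LABEL = "pMCI"


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's baseline data and optional longitudinal outcomes."""

    subject_id: str
    features: dict[str, float]
    covariates: dict[str, float]
    label: str
    outcomes: dict[str, float | bool] = field(default_factory=dict)


class Cohort:
    """Ordered collection of subject records backed by a DataFrame.

    Invariants enforced at construction: at least one record, unique subject
    ids, a valid label per row, finite baseline features, and
    ``conversion_time`` present iff ``conversion_status`` is (with positive
    times).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        feature_names: Sequence[str] = DEFAULT_FEATURES,
        covariate_names: Sequence[str] = DEFAULT_COVARIATES,
    ):
        self.feature_names = list(feature_names)
        self.covariate_names = list(covariate_names)
        self.data = data.reset_index(drop=True)
        self._validate()

    # -- construction & validation -------------------------------------------------

    def _validate(self) -> None:
        df = self.data
        if len(df) == 0:
            raise CohortValidationError("cohort must contain at least one record")
        required = ["subject_id", *self.feature_names, *self.covariate_names, "label"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        dup = df["subject_id"].astype(str).duplicated()
        if dup.any():
            ids = sorted(df.loc[dup, "subject_id"].astype(str).unique())
            raise CohortValidationError(f"duplicate subject_id(s): {', '.join(ids)}")
        bad_labels = set(df["label"].astype(str)) - VALID_LABELS
        if bad_labels:
            raise CohortValidationError(
                f"invalid label(s) {sorted(bad_labels)}; expected one of {sorted(VALID_LABELS)}"
            )
        feats = df[self.feature_names].to_numpy(dtype=float)
        if not np.isfinite(feats).all():
            rows = np.nonzero(~np.isfinite(feats).all(axis=1))[0]
            raise CohortValidationError(
                f"non-finite baseline feature(s) in row(s) {rows.tolist()}"
            )
        if "conversion_status" in df.columns or "conversion_time" in df.columns:
            status = df.get("conversion_status")
            time = df.get("conversion_time")
            has_status = (
                status.notna() if status is not None else pd.Series(False, index=df.index)
            )
            has_time = (
                time.notna() if time is not None else pd.Series(False, index=df.index)
            )
            if not has_status.equals(has_time):
                raise CohortValidationError(
                    "conversion_time must be present exactly when conversion_status is"
                )
            if time is not None and (time.dropna() <= 0).any():
                raise CohortValidationError("conversion_time must be > 0 when present")

    # -- accessors -----------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.data["subject_id"].astype(str).to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return self.data["label"].astype(str).to_numpy()

    def features(self) -> np.ndarray:
        """(n, p) float array of baseline features in ``feature_names`` order."""
        return self.data[self.feature_names].to_numpy(dtype=float)

    def covariates(self) -> np.ndarray:
        return self.data[self.covariate_names].to_numpy(dtype=float)

    def records(self) -> list[SubjectRecord]:
        out = []
        for _, row in self.data.iterrows():
            outcomes: dict[str, float | bool] = {}
            for col in OUTCOME_COLUMNS:
                if col in self.data.columns and pd.notna(row[col]):
                    val = row[col]
                    outcomes[col] = bool(val) if col == "conversion_status" else float(val)
            out.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    features={f: float(row[f]) for f in self.feature_names},
                    covariates={c: float(row[c]) for c in self.covariate_names},
                    label=str(row["label"]),
                    outcomes=outcomes,
                )
            )
        return out

    def labeled_subset(self) -> "Cohort":
        """Subjects carrying an sMCI or pMCI diagnosis (the trainable subset)."""
        mask = self.data["label"].isin([STABLE_LABEL, PROGRESSIVE_LABEL])
        if not mask.any():
            raise CohortValidationError("no sMCI/pMCI-labeled records in cohort")
        return self.replace_data(self.data.loc[mask])

    def replace_data(self, data: pd.DataFrame) -> "Cohort":
        return Cohort(data, self.feature_names, self.covariate_names)

    def with_features(self, values: np.ndarray) -> "Cohort":
        """Copy of the cohort with the feature block replaced (row order kept)."""
        if values.shape != (len(self), len(self.feature_names)):
            raise SchemaError(
                f"feature block shape {values.shape} does not match cohort "
                f"({len(self)}, {len(self.feature_names)})"
            )
        df = self.data.copy()
        df[self.feature_names] = values
        return self.replace_data(df)

    def index_of(self, subject_ids: Iterable[str]) -> np.ndarray:
        wanted = set(map(str, subject_ids))
        mask = np.isin(self.subject_ids, list(wanted))
        missing = wanted - set(self.subject_ids[mask])
        if missing:
            raise CohortValidationError(f"unknown subject id(s): {sorted(missing)}")
        return np.nonzero(mask)[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        if self.feature_names != other.feature_names:
            return False
        a = self.data.reindex(sorted(self.data.columns), axis=1)
        b = other.data.reindex(sorted(other.data.columns), axis=1)
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return True


# -- CSV I/O -----------------------------------------------------------------------


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    feature_names: Sequence[str] = DEFAULT_FEATURES,
    covariate_names: Sequence[str] = DEFAULT_COVARIATES,
) -> Cohort:
    """Read a cohort CSV, preserving row order.

    Parameters
    ----------
    path:
        CSV file with a header row.  Expected columns: ``subject_id``, the
        feature columns, ``age``, ``sex``, ``education``, ``label`` and the
        optional outcome columns.
    schema:
        Optional mapping from canonical column names to the names used in the
        file, e.g. ``{"mmse": "MMSE_bl"}``.

    Missing optional outcome cells become absent values (NaN), never zeros.
    A non-numeric cell in a mandatory numeric column raises :class:`ParseError`
    naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"cohort file not found: {path}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {v: k for k, v in (schema or {}).items()}
    raw = raw.rename(columns=rename)

    mandatory_numeric = [*feature_names, *covariate_names]
    required = ["subject_id", *mandatory_numeric, "label"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    df = pd.DataFrame({"subject_id": raw["subject_id"].astype(str)})
    for col in mandatory_numeric:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ParseError(
                f"non-numeric value {raw[col].iloc[row]!r} in column {col!r}, row {row}"
            )
        df[col] = parsed.astype(float)
    df["label"] = raw["label"].astype(str)

    for col in OUTCOME_COLUMNS:
        if col not in raw.columns:
            continue
        cell = raw[col].replace({"": None, "NA": None, "NaN": None, "nan": None})
        if col == "conversion_status":
            df[col] = cell.map(
                lambda v: None if v is None else v.strip().lower() in ("true", "1", "yes")
            )
        else:
            df[col] = pd.to_numeric(cell, errors="raise")
    return Cohort(df, feature_names, covariate_names)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV (UTF-8, '.' decimal) that `read_cohort` round-trips."""
    cohort.data.to_csv(path, index=False)


# -- covariate adjustment ----------------------------------------------------------


class CovariateAdjuster(BaseEstimator):
    """OLS covariate-deviation adjustment of baseline features.

    For each feature an OLS model ``feature ~ 1 + covariates`` is fit on a
    designated subject subset; applying the adjuster replaces each value by
    ``x - coef^T (z - z_bar_fit)`` where ``z_bar_fit`` are the fit-subset
    covariate means, so the fit-subset feature mean and the feature's original
    scale are preserved.

    Fitted attributes: ``coef_`` (n_features, n_covariates), ``intercept_``,
    ``covariate_means_``, ``feature_names_``, ``covariate_names_``,
    ``fit_subset_``.
    """

    def fit(self, cohort: Cohort, fit_subset: Iterable[str] | None = None) -> "CovariateAdjuster":
        ids = list(fit_subset) if fit_subset is not None else list(cohort.subject_ids)
        idx = cohort.index_of(ids)
        Z = cohort.covariates()[idx]
        X = cohort.features()[idx]
        n, q = Z.shape
        if n < q + 2:
            raise CohortValidationError(
                f"fit subset of size {n} too small for {q} covariates (need >= {q + 2})"
            )
        if not np.isfinite(Z).all():
            raise AdjustmentError("non-finite covariate in fit subset")
        design = np.column_stack([np.ones(n), Z])
        coefs, _, rank, _ = np.linalg.lstsq(design, X, rcond=None)
        if rank < q + 1:
            raise DegeneracyError("covariate design matrix is rank deficient")
        self.intercept_ = coefs[0].copy()
        self.coef_ = coefs[1:].T.copy()  # (n_features, n_covariates)
        self.covariate_means_ = Z.mean(axis=0)
        self.feature_names_ = list(cohort.feature_names)
        self.covariate_names_ = list(cohort.covariate_names)
        self.fit_subset_ = sorted(map(str, ids))
        return self

    def transform(self, cohort: Cohort) -> Cohort:
        if cohort.feature_names != self.feature_names_:
            raise SchemaError(
                f"cohort features {cohort.feature_names} do not match "
                f"model features {self.feature_names_}"
            )
        Z = cohort.covariates()
        bad = ~np.isfinite(Z).all(axis=1)
        if bad.any():
            sid = cohort.subject_ids[bad][0]
            raise AdjustmentError(f"missing covariate for subject {sid!r}")
        deviation = Z - self.covariate_means_
        adjusted = cohort.features() - deviation @ self.coef_.T
        return cohort.with_features(adjusted)


# CovariateModel per the domain model: the fitted adjuster carries the
# per-feature intercept/coefficients and fit-subset covariate means.
CovariateModel = CovariateAdjuster


def fit_covariate_model(
    cohort: Cohort, fit_subset: Iterable[str] | None = None
) -> CovariateModel:
    return CovariateAdjuster().fit(cohort, fit_subset)


def apply_covariate_adjustment(cohort: Cohort, model: CovariateModel) -> Cohort:
    return model.transform(cohort)


# -- standardization ---------------------------------------------------------------


class FeatureStandardizer(BaseEstimator):
    """Per-feature z-scoring with mean/sd estimated on a training subset.

    Fitted attributes: ``mean_``, ``scale_`` (population sd, ddof=0),
    ``feature_names_``.  A zero-variance feature raises
    :class:`DegeneracyError` naming the feature.
    """

    def fit(self, cohort: Cohort, fit_subset: Iterable[str] | None = None) -> "FeatureStandardizer":
        idx = (
            cohort.index_of(list(fit_subset))
            if fit_subset is not None
            else np.arange(len(cohort))
        )
        X = cohort.features()[idx]
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=0)
        zero = self.scale_ <= 0
        if zero.any():
            name = np.asarray(cohort.feature_names)[zero][0]
            raise DegeneracyError(f"feature {name!r} has zero variance on the fit subset")
        self.feature_names_ = list(cohort.feature_names)
        return self

    def transform(self, cohort: Cohort) -> Cohort:
        if cohort.feature_names != self.feature_names_:
            raise SchemaError("cohort features do not match standardizer features")
        return cohort.with_features((cohort.features() - self.mean_) / self.scale_)


Standardizer = FeatureStandardizer


def fit_standardizer(
    cohort: Cohort, fit_subset: Iterable[str] | None = None
) -> Standardizer:
    return FeatureStandardizer().fit(cohort, fit_subset)


def apply_standardizer(cohort: Cohort, s: Standardizer) -> Cohort:
    return s.transform(cohort)
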