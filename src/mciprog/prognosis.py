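"""Prognostic index by scalar projection and three-way progression strata.

The averaged ensemble defines an axis from the stable-MCI prototype
``w_s`` to the progressive-MCI prototype ``w_p``.  The raw prognostic index
of a subject with (adjusted, standardized) features ``x`` is the scalar
projection onto that axis under the averaged relevance metric ``L``:

    s(x) = (x - w_s)^T L (w_p - w_s) / (w_p - w_s)^T L (w_p - w_s)

which is affine in ``x`` and anchored so that ``s(w_s) = 0`` and
``s(w_p) = 1`` exactly.  Higher values mean greater distance from the
stable prototype along the disease axis, i.e. higher risk of future
cognitive decline.

The 0/1 boundaries can optionally be re-calibrated against observed decline
rates: subjects are split into quartile classes by their rate of cognitive
decline, a multinomial logistic model of quartile class on the raw index is
fitted, and the boundaries are moved to the index values where the
most-probable class leaves the bottom quartile (mapped to 0) and enters the
top quartile (mapped to 1).  The calibrated index ``t`` stratifies subjects
as stable (t < 0), slowly progressive (0 <= t <= 1) or rapidly progressive
(t > 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .exceptions import CalibrationError, DegeneracyError

STRATA = ("stable", "slowly_progressive", "rapidly_progressive")


def scalar_projection(
    w_s: np.ndarray, w_p: np.ndarray, lam: np.ndarray, x: np.ndarray
) -> float | np.ndarray:
    """Raw prognostic index: metric scalar projection onto the prototype axis.

    ``x`` may be a single vector or an (n, p) matrix.  Raises
    :class:`DegeneracyError` when the prototypes coincide under the metric.
    """
    w_s = np.asarray(w_s, float)
    w_p = np.asarray(w_p, float)
    lam = np.asarray(lam, float)
    axis = w_p - w_s
    denom = float(axis @ lam @ axis)
    if denom <= 0:
        raise DegeneracyError("prototype axis is degenerate under the averaged metric")
    x = np.asarray(x, float)
    s = (x - w_s) @ (lam @ axis) / denom
    return float(s) if s.ndim == 0 else s


@dataclass(frozen=True)
class BoundaryCalibration:
    """Affine recalibration of the raw index: ``t = (s - b_low)/(b_high - b_low)``."""

    b_low: float
    b_high: float
    method: str  # "prototype_anchor" or "multinomial_logistic"
    fitted_on: str = ""

    def __post_init__(self) -> None:
        if not self.b_high > self.b_low:
            raise ValueError("b_high must exceed b_low")
        if self.method not in ("prototype_anchor", "multinomial_logistic"):
            raise ValueError(f"unknown calibration method {self.method!r}")


PROTOTYPE_ANCHOR = BoundaryCalibration(0.0, 1.0, "prototype_anchor")


@dataclass(frozen=True)
class PrognosticIndex:
    """Raw projection, calibrated index and the implied progression stratum."""

    raw: float
    calibrated: float
    stratum: str


def _argmax_class(model: LogisticRegression, s: np.ndarray) -> np.ndarray:
    return model.predict(np.asarray(s, float).reshape(-1, 1)).astype(int)


def _crossing(model: LogisticRegression, lo: float, hi: float, leave: int) -> float:
    """Bisect for the smallest s in (lo, hi] whose argmax class exceeds ``leave``."""
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _argmax_class(model, np.array([mid]))[0] <= leave:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    return hi


def calibrate_boundaries(
    raw_indices: np.ndarray,
    decline_rates: np.ndarray,
    n_grid: int = 2001,
) -> BoundaryCalibration:
    """Quartile-class multinomial-logistic boundary calibration.

    ``decline_rates`` is the rate of cognitive decline (MMSE points lost per
    year; larger = faster decline).  Subjects are split into quartile classes
    by decline rate, a multinomial logistic model of class on the raw index
    is fitted, and the most-probable-class sequence along the index axis is
    scanned: ``b_low`` is the smallest index where it leaves the bottom
    quartile, ``b_high`` the smallest index where it enters the top quartile.

    Raises :class:`CalibrationError` when the most-probable-class sequence is
    degenerate or non-monotone (e.g. decline unrelated to the index); callers
    may then fall back to :data:`PROTOTYPE_ANCHOR`.
    """
    s = np.asarray(raw_indices, float)
    r = np.asarray(decline_rates, float)
    if s.shape != r.shape or s.ndim != 1:
        raise ValueError("raw_indices and decline_rates must be equal-length vectors")
    ok = np.isfinite(s) & np.isfinite(r)
    s, r = s[ok], r[ok]
    if len(s) < 40:
        raise CalibrationError(f"need >= 40 subjects with index and decline rate, got {len(s)}")
    if np.ptp(r) == 0:
        raise CalibrationError("decline rates are all equal; quartile classes undefined")

    q = np.quantile(r, [0.25, 0.5, 0.75])
    klass = np.searchsorted(q, r, side="right")  # 0..3, bottom to top quartile
    if len(np.unique(klass)) < 2:
        raise CalibrationError("quartile classes are degenerate")

    model = LogisticRegression(C=1e6, max_iter=5000)
    model.fit(s.reshape(-1, 1), klass)

    grid = np.linspace(s.min(), s.max(), n_grid)
    seq = _argmax_class(model, grid)
    if np.any(np.diff(seq) < 0):
        raise CalibrationError("most-probable quartile class is non-monotone in the index")
    if seq[0] != 0 or seq[-1] != klass.max():
        raise CalibrationError(
            "most-probable-class sequence does not span bottom to top quartile"
        )

    first_above0 = int(np.argmax(seq > 0))
    b_low = _crossing(model, grid[first_above0 - 1], grid[first_above0], leave=0)
    top = int(klass.max())
    first_top = int(np.argmax(seq >= top))
    b_high = _crossing(model, grid[first_top - 1], grid[first_top], leave=top - 1)
    if not b_high > b_low:
        raise CalibrationError("calibrated boundaries are not ordered")
    return BoundaryCalibration(
        float(b_low), float(b_high), "multinomial_logistic", fitted_on=f"n={len(s)}"
    )


def apply_calibration(s: float | np.ndarray, cal: BoundaryCalibration) -> float | np.ndarray:
    """Map a raw index to the calibrated scale; strictly increasing in ``s``."""
    s = np.asarray(s, float)
    t = (s - cal.b_low) / (cal.b_high - cal.b_low)
    return float(t) if t.ndim == 0 else t


def stratify(t: float) -> str:
    """Progression stratum from the calibrated index.

    Below 0 → stable; 0 through 1 inclusive → slowly progressive; above 1 →
    rapidly progressive.
    """
    if not np.isfinite(t):
        raise ValueError(f"calibrated index must be finite, got {t}")
    if t < 0:
        return "stable"
    if t <= 1:
        return "slowly_progressive"
    return "rapidly_progressive"


def prognostic_index(
    raw: float, cal: BoundaryCalibration = PROTOTYPE_ANCHOR
) -> PrognosticIndex:
    t = float(apply_calibration(raw, cal))
    return PrognosticIndex(raw=float(raw), calibrated=t, stratum=stratify(t))
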