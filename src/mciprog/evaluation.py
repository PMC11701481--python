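"""Cross-validated performance estimation and nested hyper-parameter tuning.

The evaluation protocol is repeated stratified k-fold cross-validation
(default 10 iterations of 10 folds).  Within every fold the full pipeline —
covariate adjustment, standardization, balanced resampling, ensemble
training and member selection — is fit on the training portion only, and
majority-vote predictions plus continuous ensemble scores are computed on
the held-out fold.  Metrics (balanced accuracy, sensitivity, specificity,
AUC; progressive MCI is the positive class) are aggregated per iteration,
and 95% confidence half-widths across iterations use the t distribution.

Hyper-parameter tuning is nested: an inner k'-fold cross-validation (default
5) on each outer-fold training portion scores every candidate learning-rate
pair by mean balanced accuracy; the modal winning pair across outer folds is
returned.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .cohort import Cohort, PROGRESSIVE_LABEL
from .exceptions import ClassBalanceError, StratificationError
from .pipeline import ProgressionModel


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with progressive MCI as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    t = np.asarray(y_true).astype(str) == PROGRESSIVE_LABEL
    p = np.asarray(y_pred).astype(str) == PROGRESSIVE_LABEL
    return ConfusionCounts(
        tp=int((t & p).sum()),
        fp=int((~t & p).sum()),
        tn=int((~t & ~p).sum()),
        fn=int((t & ~p).sum()),
    )


def confusion_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity %, specificity %, balanced accuracy %)."""
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise ClassBalanceError("a class is empty; sensitivity/specificity undefined")
    sens = 100.0 * counts.tp / (counts.tp + counts.fn)
    spec = 100.0 * counts.tn / (counts.tn + counts.fp)
    return sens, spec, (sens + spec) / 2.0


def auc_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC with the Mann–Whitney midrank convention for ties.

    ``labels`` may be boolean or the sMCI/pMCI strings (pMCI positive).
    """
    labels = np.asarray(labels)
    if labels.dtype.kind in "UOS":
        labels = labels.astype(str) == PROGRESSIVE_LABEL
    labels = labels.astype(bool)
    if labels.all() or not labels.any():
        raise ClassBalanceError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


@dataclass(frozen=True)
class CvConfig:
    k: int = 10
    iterations: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2 or self.iterations < 1:
            raise ValueError("need k >= 2 and iterations >= 1")


@dataclass
class MetricReport:
    """Per-iteration and pooled cross-validation metrics with 95% CIs."""

    per_fold: pd.DataFrame  # iteration, fold, tp/fp/tn/fn, n_test
    per_iteration: pd.DataFrame  # balanced_accuracy, sensitivity, specificity, auc
    pooled: dict[str, float]
    mean: dict[str, float]
    ci_half_width: dict[str, float]
    config: CvConfig = field(default_factory=CvConfig)

    def summary(self) -> dict:
        return {
            "pooled": self.pooled,
            "mean": self.mean,
            "ci_half_width": self.ci_half_width,
            "iterations": int(self.config.iterations),
            "k": int(self.config.k),
            "seed": int(self.config.seed),
        }


_METRICS = ("balanced_accuracy", "sensitivity", "specificity", "auc")


def _fold_seed(base: int, iteration: int, fold: int) -> int:
    return (base + 7919 * iteration + 104729 * fold) % (2**31 - 1)


def cross_validate(
    cohort: Cohort,
    cv: CvConfig = CvConfig(),
    **model_params,
) -> MetricReport:
    """Repeated stratified k-fold evaluation of the full pipeline.

    ``model_params`` are forwarded to :class:`ProgressionModel` (e.g.
    ``n_resamples``, ``alpha_w``).  Deterministic given ``cv.seed``.
    """
    data = cohort.labeled_subset()
    y = data.labels
    counts = Counter(y)
    if min(counts.values()) < cv.k:
        raise StratificationError(
            f"smallest class ({min(counts.values())}) is below k={cv.k}"
        )

    fold_rows = []
    iter_rows = []
    for it in range(cv.iterations):
        splitter = StratifiedKFold(
            n_splits=cv.k, shuffle=True, random_state=(cv.seed + 131 * it) % (2**31 - 1)
        )
        iter_counts = ConfusionCounts(0, 0, 0, 0)
        iter_scores: list[np.ndarray] = []
        iter_labels: list[np.ndarray] = []
        for fold, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
            train = data.replace_data(data.data.iloc[train_idx])
            test = data.replace_data(data.data.iloc[test_idx])
            model = ProgressionModel(
                **model_params, random_state=_fold_seed(cv.seed, it, fold)
            ).fit(train)
            pred = model.predict(test)
            scores = model.decision_function(test)
            cc = confusion_counts(test.labels, pred)
            iter_counts = iter_counts + cc
            iter_scores.append(scores)
            iter_labels.append(test.labels)
            fold_rows.append(
                {
                    "iteration": it,
                    "fold": fold,
                    "tp": cc.tp,
                    "fp": cc.fp,
                    "tn": cc.tn,
                    "fn": cc.fn,
                    "n_test": len(test_idx),
                }
            )
        sens, spec, bal = confusion_metrics(iter_counts)
        auc = auc_from_scores(np.concatenate(iter_scores), np.concatenate(iter_labels))
        iter_rows.append(
            {
                "iteration": it,
                "balanced_accuracy": bal,
                "sensitivity": sens,
                "specificity": spec,
                "auc": auc,
            }
        )

    per_fold = pd.DataFrame(fold_rows)
    per_iteration = pd.DataFrame(iter_rows)
    total = ConfusionCounts(
        int(per_fold.tp.sum()), int(per_fold.fp.sum()), int(per_fold.tn.sum()), int(per_fold.fn.sum())
    )
    sens, spec, bal = confusion_metrics(total)
    pooled = {
        "balanced_accuracy": bal,
        "sensitivity": sens,
        "specificity": spec,
        "auc": float(per_iteration.auc.mean()),
    }
    mean = {m: float(per_iteration[m].mean()) for m in _METRICS}
    if cv.iterations > 1:
        tcrit = float(stats.t.ppf(0.975, cv.iterations - 1))
        ci = {
            m: tcrit * float(per_iteration[m].std(ddof=1)) / np.sqrt(cv.iterations)
            for m in _METRICS
        }
    else:
        ci = {m: float("nan") for m in _METRICS}
    return MetricReport(
        per_fold=per_fold,
        per_iteration=per_iteration,
        pooled=pooled,
        mean=mean,
        ci_half_width=ci,
        config=cv,
    )


def nested_tune(
    cohort: Cohort,
    grid: list[tuple[float, float]],
    cv: CvConfig = CvConfig(),
    inner_k: int = 5,
    **model_params,
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Nested-CV selection of the (alpha_w, alpha_omega) learning-rate pair.

    Returns the modal per-outer-fold winner and the full inner-CV score
    table.  Ties prefer smaller learning rates (alpha_w + alpha_omega), then
    grid order.  Candidate pairs that diverge on an inner fold score 0 for
    that fold, so a consistently divergent pair is never selected.
    """
    if not grid:
        raise ValueError("hyper-parameter grid must be non-empty")
    data = cohort.labeled_subset()
    y = data.labels
    if min(Counter(y).values()) < cv.k:
        raise StratificationError("smallest class is below the outer fold count")

    outer = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed % (2**31 - 1))
    rows = []
    winners: list[tuple[float, float]] = []
    grid_order = {pair: i for i, pair in enumerate(grid)}
    for ofold, (tr_idx, _) in enumerate(outer.split(np.zeros(len(y)), y)):
        train = data.replace_data(data.data.iloc[tr_idx])
        ty = train.labels
        inner = StratifiedKFold(
            n_splits=inner_k,
            shuffle=True,
            random_state=(cv.seed + 977 * ofold) % (2**31 - 1),
        )
        mean_scores = {}
        for pair in grid:
            aw, ao = pair
            scores = []
            for ifold, (itr, ival) in enumerate(inner.split(np.zeros(len(ty)), ty)):
                itrain = train.replace_data(train.data.iloc[itr])
                ival_cohort = train.replace_data(train.data.iloc[ival])
                try:
                    model = ProgressionModel(
                        **model_params,
                        alpha_w=aw,
                        alpha_omega=ao,
                        random_state=_fold_seed(cv.seed, ofold, ifold),
                    ).fit(itrain)
                    _, _, bal = confusion_metrics(
                        confusion_counts(ival_cohort.labels, model.predict(ival_cohort))
                    )
                except Exception:  # divergence or degenerate fold: score zero
                    bal = 0.0
                scores.append(bal)
            mean_scores[pair] = float(np.mean(scores))
            rows.append(
                {
                    "outer_fold": ofold,
                    "alpha_w": aw,
                    "alpha_omega": ao,
                    "mean_inner_balanced_accuracy": mean_scores[pair],
                }
            )
        best = min(
            grid,
            key=lambda pr: (-mean_scores[pr], pr[0] + pr[1], grid_order[pr]),
        )
        winners.append(best)

    tally = Counter(winners)
    best_pair = min(
        tally,
        key=lambda pr: (-tally[pr], pr[0] + pr[1], grid_order[pr]),
    )
    return best_pair, pd.DataFrame(rows)


def average_member_performance(ensemble, X: np.ndarray, y: np.ndarray) -> float:
    """Mean balanced accuracy (%) of the selected members on labeled test data."""
    models = ensemble._selected_models()
    vals = []
    for m in models:
        _, _, bal = confusion_metrics(confusion_counts(y, m.predict(X)))
        vals.append(bal)
    return float(np.mean(vals))
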