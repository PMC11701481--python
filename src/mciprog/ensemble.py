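"""Class-balancing resampling ensemble of GMLVQ classifiers.

Clinical cohorts are imbalanced (stable MCI typically outnumbers progressive
MCI).  Rather than reweighting, the ensemble repeatedly down-samples the
majority class to the minority size (default 400 balanced resamples), trains
one GMLVQ classifier per resample, ranks members by balanced accuracy on the
full training sample, keeps the top fraction (default 20%), and predicts by
majority vote.  The selected members' class prototypes and unit-trace
relevance matrices are arithmetically averaged; the averaged model defines
the prototype axis used for the prognostic index and resolves exact vote
ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import balanced_accuracy_score

from .exceptions import ClassBalanceError, SelectionError
from .gmlvq import GmlvqClassifier, GmlvqHyper, _pairwise_sq_distances, train_gmlvq


@dataclass(frozen=True)
class ResamplePlan:
    """Deterministic plan of balanced resamples.

    Each index set contains every minority-class subject exactly once plus an
    equal-sized majority-class subset drawn without replacement, so all sets
    have size ``2 * n_minority``.  Member ``i`` trains with seed
    ``seed + i``.
    """

    n_resamples: int
    index_sets: tuple[tuple[int, ...], ...]
    member_seeds: tuple[int, ...]


def make_resamples(labels: np.ndarray, n_resamples: int = 400, seed: int = 0) -> ResamplePlan:
    """Build a :class:`ResamplePlan` for the given label vector.

    Deterministic given (label order, n_resamples, seed).  With perfectly
    balanced labels every index set is the full sample.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    labels = np.asarray(labels).astype(str)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ClassBalanceError("labels must contain both classes")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    if minority == majority:  # equal counts: argmin==argmax index
        minority, majority = classes[0], classes[1]
    min_idx = np.nonzero(labels == minority)[0]
    maj_idx = np.nonzero(labels == majority)[0]
    n_min = len(min_idx)

    rng = np.random.default_rng(seed)
    index_sets = []
    for _ in range(n_resamples):
        sampled = rng.choice(maj_idx, size=n_min, replace=False)
        merged = np.sort(np.concatenate([min_idx, sampled]))
        index_sets.append(tuple(int(i) for i in merged))
    return ResamplePlan(
        n_resamples=n_resamples,
        index_sets=tuple(index_sets),
        member_seeds=tuple(seed + i for i in range(n_resamples)),
    )


@dataclass
class EnsembleMember:
    model: GmlvqClassifier
    train_balanced_accuracy: float
    seed: int


class BalancedGmlvqEnsemble(ClassifierMixin, BaseEstimator):
    """Ensemble of GMLVQ classifiers over balanced resamples.

    Parameters mirror :class:`GmlvqClassifier` plus ``n_resamples`` and
    ``selection_fraction``.  ``fit`` expects features that have already been
    covariate-adjusted and standardized (see :mod:`mciprog.pipeline` for the
    end-to-end model).

    Attributes
    ----------
    members_ : list of :class:`EnsembleMember`, in resample-plan order.
    selected_ : boolean flags; exactly ``round(selection_fraction * n_resamples)``
        are set.
    averaged_prototypes_ : (2, p) mean prototypes over selected members.
    averaged_lambda_ : (p, p) mean relevance matrix (unit trace, no
        renormalization needed — a mean of unit-trace matrices has unit trace).
    """

    def __init__(
        self,
        n_resamples: int = 400,
        selection_fraction: float = 0.20,
        alpha_w: float = 0.1,
        alpha_omega: float = 0.05,
        epochs: int = 300,
        jitter_sd: float = 0.0,
        random_state: int = 0,
    ):
        self.n_resamples = n_resamples
        self.selection_fraction = selection_fraction
        self.alpha_w = alpha_w
        self.alpha_omega = alpha_omega
        self.epochs = epochs
        self.jitter_sd = jitter_sd
        self.random_state = random_state

    def _hyper(self, seed: int) -> GmlvqHyper:
        return GmlvqHyper(
            alpha_w=self.alpha_w,
            alpha_omega=self.alpha_omega,
            epochs=self.epochs,
            jitter_sd=self.jitter_sd,
            seed=seed,
        )

    def fit(
        self, X: np.ndarray, y: np.ndarray, plan: ResamplePlan | None = None
    ) -> "BalancedGmlvqEnsemble":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(str)
        if plan is None:
            plan = make_resamples(y, self.n_resamples, self.random_state)
        if plan.index_sets and max(max(s) for s in plan.index_sets) >= len(X):
            raise IndexError("resample plan indices exceed cohort size")
        self.plan_ = plan
        self.members_ = []
        for i, (idx_set, seed) in enumerate(zip(plan.index_sets, plan.member_seeds)):
            idx = np.asarray(idx_set)
            try:
                model = train_gmlvq(X[idx], y[idx], self._hyper(seed))
            except Exception as exc:  # annotate with the member index
                raise type(exc)(f"member {i}: {exc}") from exc
            # rank on the FULL training sample, not the member's own resample
            bal = balanced_accuracy_score(y, model.predict(X))
            self.members_.append(EnsembleMember(model, float(bal), seed))
        self.classes_ = self.members_[0].model.classes_
        self.n_features_in_ = X.shape[1]
        self._select(self.selection_fraction)
        return self

    # -- selection -----------------------------------------------------------------

    def _select(self, fraction: float) -> None:
        if not 0 < fraction <= 1:
            raise SelectionError("selection fraction must be in (0, 1]")
        n = len(self.members_)
        k = int(np.floor(fraction * n + 0.5))
        if k == 0:
            raise SelectionError(f"fraction {fraction} selects zero of {n} members")
        # rank: higher balanced accuracy, then lower final cost, then lower index
        order = sorted(
            range(n),
            key=lambda i: (
                -self.members_[i].train_balanced_accuracy,
                self.members_[i].model.cost_trace_[-1],
                i,
            ),
        )
        selected = np.zeros(n, dtype=bool)
        selected[order[:k]] = True
        self.selected_ = selected
        self.selection_fraction_ = fraction
        chosen = [self.members_[i].model for i in np.nonzero(selected)[0]]
        self.averaged_prototypes_ = np.mean([m.prototypes_ for m in chosen], axis=0)
        self.averaged_lambda_ = np.mean([m.lambda_ for m in chosen], axis=0)

    def select_top(self, fraction: float) -> "BalancedGmlvqEnsemble":
        """Re-flag the top ``round(fraction * n)`` members and re-average."""
        self._select(fraction)
        return self

    # -- prediction ----------------------------------------------------------------

    def _selected_models(self) -> list[GmlvqClassifier]:
        if not hasattr(self, "selected_") or not self.selected_.any():
            raise SelectionError("ensemble has no selected members")
        return [self.members_[i].model for i in np.nonzero(self.selected_)[0]]

    def _averaged_distances(self, X: np.ndarray) -> np.ndarray:
        return _pairwise_sq_distances(
            np.asarray(X, float), self.averaged_prototypes_, self.averaged_lambda_
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Majority vote of the selected members.

        An exact vote tie is resolved by the averaged model (nearer averaged
        prototype under the averaged relevance matrix); a residual distance
        tie goes to the progressive class.
        """
        X = np.asarray(X, dtype=float)
        models = self._selected_models()
        votes_pos = np.zeros(len(X), dtype=int)
        for m in models:
            votes_pos += (m.predict(X) == self.classes_[1]).astype(int)
        n_models = len(models)
        out = np.where(votes_pos * 2 > n_models, self.classes_[1], self.classes_[0])
        tie = votes_pos * 2 == n_models
        if tie.any():
            d = self._averaged_distances(X[tie])
            out[tie] = np.where(d[:, 1] <= d[:, 0] + 1e-12, self.classes_[1], self.classes_[0])
        return out.astype(object)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Continuous ensemble score in [-1, 1].

        Mean over selected members of the signed relative margin
        ``(d_neg - d_pos)/(d_neg + d_pos)``; positive values indicate
        proximity to the progressive prototype.  Monotone input to the AUC.
        """
        X = np.asarray(X, dtype=float)
        models = self._selected_models()
        scores = np.zeros(len(X))
        for m in models:
            scores += m.decision_function(X)
        return scores / len(models)


# -- functional wrappers -----------------------------------------------------------


def train_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    hyper: GmlvqHyper,
    plan: ResamplePlan,
    selection_fraction: float = 0.20,
) -> BalancedGmlvqEnsemble:
    ens = BalancedGmlvqEnsemble(
        n_resamples=plan.n_resamples,
        selection_fraction=selection_fraction,
        alpha_w=hyper.alpha_w,
        alpha_omega=hyper.alpha_omega,
        epochs=hyper.epochs,
        jitter_sd=hyper.jitter_sd,
        random_state=hyper.seed,
    )
    return ens.fit(X, y, plan=plan)


def select_top(ensemble: BalancedGmlvqEnsemble, fraction: float) -> BalancedGmlvqEnsemble:
    return ensemble.select_top(fraction)


def predict_majority(ensemble: BalancedGmlvqEnsemble, x: np.ndarray) -> str:
    return str(ensemble.predict(np.atleast_2d(np.asarray(x, float)))[0])


def ensemble_score(ensemble: BalancedGmlvqEnsemble, x: np.ndarray) -> float:
    return float(ensemble.decision_function(np.atleast_2d(np.asarray(x, float)))[0])
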