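"""Generalized Matrix Learning Vector Quantization (GMLVQ), binary case.

A GMLVQ classifier represents each class by a prototype ``w`` in feature
space and measures closeness with an adaptive quadratic metric

    d(x, w) = (x - w)^T Lambda (x - w),        Lambda = Omega^T Omega,

where ``Omega`` is a full p-by-p matrix learned jointly with the prototypes.
After normalization to unit trace, the diagonal of ``Lambda`` ranks the
per-feature relevance for the classification task and the off-diagonal
terms expose pairwise feature interactions — the interpretability payoff of
the method.

Training minimizes the GLVQ cost, the sum over samples of the relative
margin

    mu = (d_J - d_K) / (d_J + d_K)  in  [-1, 1],

with ``d_J`` the distance to the correct-class prototype and ``d_K`` the
distance to the other class's prototype; ``mu < 0`` means the sample is on
the correct side of the decision boundary.  The identity link ``phi(mu) =
mu`` is used, so the only tuned hyper-parameters are the two learning rates.
Optimization is deterministic full-batch gradient descent; after every
metric update ``Omega`` is rescaled so that ``trace(Lambda) = 1``, which
leaves every margin (and hence the cost) unchanged because ``mu`` is
invariant to a global rescaling of the metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .exceptions import ClassBalanceError, DegeneracyError, DivergenceError

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class GmlvqHyper:
    """Hyper-parameters of a single GMLVQ fit.

    alpha_w / alpha_omega are per-sample learning rates for prototypes and
    for the metric; jitter_sd is the s.d. of Gaussian noise added to the
    class-conditional-mean prototype initialization.
    """

    alpha_w: float = 0.1
    alpha_omega: float = 0.05
    epochs: int = 300
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_w <= 0 or self.alpha_omega < 0:
            raise ValueError("learning rates must be positive (alpha_omega may be 0)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


# -- functional primitives ---------------------------------------------------------


def relevance_matrix(omega: np.ndarray) -> np.ndarray:
    """Unit-trace relevance matrix ``Lambda = Omega^T Omega / tr(Omega^T Omega)``.

    Symmetric and PSD by construction; its diagonal sums to one.
    """
    omega = np.asarray(omega, dtype=float)
    gram = omega.T @ omega
    tr = np.trace(gram)
    if tr <= 0:
        raise DegeneracyError("Omega^T Omega has non-positive trace (zero matrix?)")
    return gram / tr


def metric_distance(x: np.ndarray, w: np.ndarray, lam: np.ndarray) -> float:
    """Quadratic distance ``(x - w)^T Lambda (x - w)`` (>= 0 for PSD Lambda)."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if x.shape != w.shape or lam.shape != (x.size, x.size):
        raise ValueError(
            f"dimension mismatch: x {x.shape}, w {w.shape}, lambda {lam.shape}"
        )
    diff = x - w
    return float(diff @ lam @ diff)


def relative_margin(d_correct: float, d_wrong: float) -> float:
    """GLVQ relative margin ``(d_J - d_K)/(d_J + d_K)``; negative = correct side."""
    total = d_correct + d_wrong
    if total <= 0:
        raise DegeneracyError("both distances are zero; margin undefined")
    return (d_correct - d_wrong) / total


def _pairwise_sq_distances(X: np.ndarray, prototypes: np.ndarray, metric: np.ndarray) -> np.ndarray:
    """(n, n_prototypes) matrix of quadratic distances under ``metric``."""
    diff = X[:, None, :] - prototypes[None, :, :]
    return np.einsum("ncp,pq,ncq->nc", diff, metric, diff)


def _margins(prototypes: np.ndarray, omega: np.ndarray, X: np.ndarray, y_idx: np.ndarray):
    """Per-sample margins and the intermediates the gradients need.

    Distances use the *pre-normalization* metric ``Omega^T Omega`` (margins
    are invariant to the trace normalization, so the cost is unaffected).
    """
    metric = omega.T @ omega
    d = _pairwise_sq_distances(X, prototypes, metric)
    n = len(X)
    rows = np.arange(n)
    d_correct = d[rows, y_idx]
    d_wrong = d[rows, 1 - y_idx]
    total = d_correct + d_wrong
    if np.any(total <= 0):
        raise DegeneracyError("a sample coincides with both prototypes")
    mu = (d_correct - d_wrong) / total
    return mu, d_correct, d_wrong, metric


def glvq_cost(model: "GmlvqClassifier", X: np.ndarray, y: np.ndarray) -> float:
    """Summed GLVQ cost ``sum_i mu_i`` (identity link), in ``[-n, n]``."""
    y_idx = model._encode(y)
    mu, *_ = _margins(model.prototypes_, model.omega_, np.asarray(X, float), y_idx)
    return float(mu.sum())


def _cost_gradients(
    prototypes: np.ndarray, omega: np.ndarray, X: np.ndarray, y_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of the summed cost w.r.t. (w_0, w_1, Omega).

    Per sample: dmu/dd_J = 2 d_K / (d_J + d_K)^2, dmu/dd_K = -2 d_J /
    (d_J + d_K)^2, dd/dw = -2 (Omega^T Omega)(x - w), and
    dd/dOmega = 2 Omega (x - w)(x - w)^T, chain-ruled and summed.
    """
    mu, d_correct, d_wrong, metric = _margins(prototypes, omega, X, y_idx)
    return _gradients_from_margins(prototypes, omega, X, y_idx, mu, d_correct, d_wrong, metric)[:3]


def _gradients_from_margins(prototypes, omega, X, y_idx, mu, d_correct, d_wrong, metric):
    total_sq = (d_correct + d_wrong) ** 2
    a = 2.0 * d_wrong / total_sq  # dmu/dd_J
    b = -2.0 * d_correct / total_sq  # dmu/dd_K

    u = X - prototypes[y_idx]  # displacement from correct prototype
    v = X - prototypes[1 - y_idx]  # displacement from wrong prototype

    grad_w = np.zeros_like(prototypes)
    for c in (0, 1):
        correct_here = y_idx == c
        # dd_J/dw_c for samples whose correct class is c, dd_K/dw_c otherwise
        contrib = np.where(correct_here[:, None], a[:, None] * u, b[:, None] * v)
        grad_w[c] = -2.0 * metric @ contrib.sum(axis=0)

    grad_omega = 2.0 * omega @ ((u * a[:, None]).T @ u + (v * b[:, None]).T @ v)
    return grad_w[0], grad_w[1], grad_omega, mu


def cost_gradients(model: "GmlvqClassifier", X: np.ndarray, y: np.ndarray):
    """Gradients of :func:`glvq_cost` w.r.t. ``(w_neg, w_pos, Omega)``."""
    y_idx = model._encode(y)
    return _cost_gradients(model.prototypes_, model.omega_, np.asarray(X, float), y_idx)


def numerical_cost_gradient(
    model: "GmlvqClassifier", X: np.ndarray, y: np.ndarray, h: float = 1e-5
):
    """Central-finite-difference gradients of :func:`glvq_cost` (test oracle).

    Perturbs every coordinate of both prototypes and of Omega by +-h and
    differences the cost; O(h^2) accurate on smooth instances.
    """
    if h <= 0:
        raise ValueError("h must be > 0")
    X = np.asarray(X, float)
    y_idx = model._encode(y)

    def cost_at(prototypes: np.ndarray, omega: np.ndarray) -> float:
        mu, *_ = _margins(prototypes, omega, X, y_idx)
        return float(mu.sum())

    grads = []
    for which in ("w0", "w1", "omega"):
        base = model.omega_ if which == "omega" else model.prototypes_[int(which[1])]
        g = np.zeros_like(base)
        it = np.nditer(base, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            for sign in (+1.0, -1.0):
                prototypes = model.prototypes_.copy()
                omega = model.omega_.copy()
                if which == "omega":
                    omega[idx] += sign * h
                else:
                    prototypes[int(which[1])][idx] += sign * h
                g[idx] += sign * cost_at(prototypes, omega)
        grads.append(g / (2.0 * h))
    return tuple(grads)


# -- estimator ---------------------------------------------------------------------


class GmlvqClassifier(ClassifierMixin, BaseEstimator):
    """Binary GMLVQ classifier with one prototype per class.

    Parameters
    ----------
    alpha_w, alpha_omega:
        Per-sample learning rates for prototype and metric updates (the two
        tuned hyper-parameters).
    epochs:
        Number of full-batch gradient-descent epochs.
    jitter_sd:
        S.d. of seeded Gaussian jitter added to the class-conditional-mean
        prototype initialization.
    random_state:
        Seed for the jitter draw; training is deterministic given
        (data order, parameters, seed).

    Attributes
    ----------
    classes_ : (2,) array — (negative, positive) class order.  When the
        labels are the MCI outcome labels this is ``('sMCI', 'pMCI')``;
        otherwise sorted order with the second class treated as positive.
    prototypes_ : (2, p) array, rows aligned with ``classes_``.
    omega_ : (p, p) metric square root, kept at unit-trace ``Omega^T Omega``.
    lambda_ : (p, p) unit-trace PSD relevance matrix.
    cost_trace_ : per-epoch summed GLVQ cost.
    """

    def __init__(
        self,
        alpha_w: float = 0.1,
        alpha_omega: float = 0.05,
        epochs: int = 300,
        jitter_sd: float = 0.0,
        random_state: int | None = 0,
    ):
        self.alpha_w = alpha_w
        self.alpha_omega = alpha_omega
        self.epochs = epochs
        self.jitter_sd = jitter_sd
        self.random_state = random_state

    # ordered (negative, positive); pMCI is the positive (progressive) class
    @staticmethod
    def _class_order(labels: np.ndarray) -> np.ndarray:
        uniq = set(map(str, labels))
        if uniq == {"sMCI", "pMCI"}:
            return np.asarray(["sMCI", "pMCI"], dtype=object)
        return np.asarray(sorted(uniq), dtype=object)

    def _encode(self, y: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "classes_")
        y = np.asarray(y)
        idx = np.searchsorted(self._class_codes_, y.astype(str))
        valid = (idx < 2) & (self._class_codes_[np.minimum(idx, 1)] == y.astype(str))
        if not valid.all():
            bad = y[~valid][0]
            raise ClassBalanceError(f"label {bad!r} not in {tuple(self.classes_)}")
        return self._order_lookup_[idx]

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GmlvqClassifier":
        hyper = GmlvqHyper(
            alpha_w=self.alpha_w,
            alpha_omega=self.alpha_omega,
            epochs=self.epochs,
            jitter_sd=self.jitter_sd,
            seed=self.random_state if self.random_state is not None else 0,
        )
        X, y = check_X_y(X, y, dtype=float, ensure_min_samples=4)
        classes = self._class_order(y)
        if len(set(map(str, y))) < 2:
            raise ClassBalanceError("training data must contain both classes")
        self.classes_ = classes
        self._class_codes_ = np.sort(classes.astype(str))
        self._order_lookup_ = np.array(
            [int(np.nonzero(classes.astype(str) == c)[0][0]) for c in self._class_codes_]
        )
        y_idx = self._encode(y)
        n, p = X.shape

        rng = np.random.default_rng(hyper.seed)
        prototypes = np.stack([X[y_idx == c].mean(axis=0) for c in (0, 1)])
        prototypes = prototypes + rng.normal(0.0, hyper.jitter_sd, size=prototypes.shape)
        omega = np.eye(p) / np.sqrt(p)  # Lambda starts at I/p

        # cost_trace[k] is the cost entering epoch k; a final entry after the
        # last update is appended below, so the trace has epochs + 1 values.
        cost_trace = []
        for epoch in range(hyper.epochs):
            mu, d_correct, d_wrong, metric = _margins(prototypes, omega, X, y_idx)
            cost = float(mu.sum())
            if not np.isfinite(cost) or not np.isfinite(prototypes).all():
                raise DivergenceError(f"non-finite cost at epoch {epoch}")
            cost_trace.append(cost)
            g0, g1, gom, _ = _gradients_from_margins(
                prototypes, omega, X, y_idx, mu, d_correct, d_wrong, metric
            )
            # per-sample steps: summed gradients scaled by 1/n
            prototypes[0] -= hyper.alpha_w * g0 / n
            prototypes[1] -= hyper.alpha_w * g1 / n
            omega -= hyper.alpha_omega * gom / n
            tr = np.trace(omega.T @ omega)
            if not np.isfinite(tr) or tr <= 0:
                raise DivergenceError(f"metric degenerated at epoch {epoch}")
            omega /= np.sqrt(tr)
        mu, *_ = _margins(prototypes, omega, X, y_idx)
        if not np.isfinite(mu).all():
            raise DivergenceError(f"non-finite cost at epoch {hyper.epochs}")
        cost_trace.append(float(mu.sum()))

        self.prototypes_ = prototypes
        self.omega_ = omega
        self.lambda_ = relevance_matrix(omega)
        self.cost_trace_ = np.asarray(cost_trace)
        self.n_features_in_ = p
        self.hyper_ = hyper
        return self

    def _distances(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "prototypes_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model expects {self.n_features_in_}"
            )
        return _pairwise_sq_distances(X, self.prototypes_, self.lambda_)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Signed score ``(d_neg - d_pos)/(d_neg + d_pos)``; positive → positive class."""
        d = self._distances(X)
        total = d.sum(axis=1)
        if np.any(total <= 0):
            raise DegeneracyError("a sample coincides with both prototypes")
        return (d[:, 0] - d[:, 1]) / total

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self._distances(X)
        # ties (within 1e-12) go to the progressive class, favoring sensitivity
        pos = d[:, 1] <= d[:, 0] + _TIE_TOL
        return self.classes_[pos.astype(int)]


# -- functional training interface -------------------------------------------------


def train_gmlvq(X: np.ndarray, y: np.ndarray, hyper: GmlvqHyper | None = None) -> GmlvqClassifier:
    """Train a GMLVQ model; thin wrapper over :class:`GmlvqClassifier`."""
    hyper = hyper or GmlvqHyper()
    clf = GmlvqClassifier(
        alpha_w=hyper.alpha_w,
        alpha_omega=hyper.alpha_omega,
        epochs=hyper.epochs,
        jitter_sd=hyper.jitter_sd,
        random_state=hyper.seed,
    )
    return clf.fit(X, y)


def predict(model: GmlvqClassifier, x: np.ndarray) -> tuple[str, float, float]:
    """Nearest-prototype label and the two distances ``(label, d_neg, d_pos)``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    d = model._distances(x)[0]
    label = model.classes_[1] if d[1] <= d[0] + _TIE_TOL else model.classes_[0]
    return str(label), float(d[0]), float(d[1])
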