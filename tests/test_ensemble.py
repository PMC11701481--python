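"""Balanced resampling plans, ensemble training, selection, voting, scoring."""

import numpy as np
import pytest

from mciprog import (
    BalancedGmlvqEnsemble,
    GmlvqHyper,
    make_resamples,
    train_ensemble,
    train_gmlvq,
)
from mciprog.ensemble import EnsembleMember
from mciprog.exceptions import ClassBalanceError, SelectionError
from mciprog.gmlvq import GmlvqClassifier, relevance_matrix
from sklearn.metrics import balanced_accuracy_score


def labels(n_s, n_p):
    return np.array(["sMCI"] * n_s + ["pMCI"] * n_p)


class TestResamplePlan:
    def test_reference_sizes_each_set_balanced(self):
        y = labels(290, 120)
        plan = make_resamples(y, n_resamples=400, seed=0)
        assert plan.n_resamples == 400
        minority = set(np.nonzero(y == "pMCI")[0])
        for idx_set in plan.index_sets:
            assert len(idx_set) == 240
            chosen = np.asarray(idx_set)
            assert minority <= set(chosen)  # every minority subject exactly once
            assert len(set(idx_set)) == 240  # no replacement
            assert (y[chosen] == "pMCI").sum() == 120

    def test_balanced_labels_use_full_sample(self):
        plan = make_resamples(labels(10, 10), n_resamples=5, seed=1)
        for idx_set in plan.index_sets:
            assert idx_set == tuple(range(20))

    def test_deterministic_and_seed_offsets(self):
        y = labels(30, 12)
        p1 = make_resamples(y, 20, seed=9)
        p2 = make_resamples(y, 20, seed=9)
        assert p1 == p2
        assert p1.member_seeds == tuple(9 + i for i in range(20))

    def test_single_class_rejected(self):
        with pytest.raises(ClassBalanceError):
            make_resamples(labels(10, 0), 5, seed=0)


def separable_data(rng, n_s=30, n_p=12, gap=6.0):
    X = rng.normal(size=(n_s + n_p, 3)) * 0.5
    X[n_s:, 0] -= gap
    return X, labels(n_s, n_p)


class TestTrainAndSelect:
    def test_single_member_separable_perfect(self, rng):
        X, y = separable_data(rng)
        plan = make_resamples(y, 1, seed=0)
        ens = train_ensemble(X, y, GmlvqHyper(epochs=80), plan, selection_fraction=1.0)
        assert len(ens.members_) == 1
        assert ens.members_[0].train_balanced_accuracy == 1.0

    def test_selection_count_and_fraction_one(self, rng):
        X, y = separable_data(rng)
        plan = make_resamples(y, 10, seed=0)
        ens = train_ensemble(X, y, GmlvqHyper(epochs=40), plan, selection_fraction=0.2)
        assert ens.selected_.sum() == 2
        ens.select_top(1.0)
        assert ens.selected_.sum() == 10

    def test_zero_selection_rejected(self, rng):
        X, y = separable_data(rng)
        ens = BalancedGmlvqEnsemble(n_resamples=4, epochs=20, random_state=0).fit(X, y)
        with pytest.raises(SelectionError):
            ens.select_top(0.01)

    def test_averaged_lambda_trace_exactly_one(self, rng):
        X, y = separable_data(rng)
        ens = BalancedGmlvqEnsemble(n_resamples=8, epochs=40, random_state=1).fit(X, y)
        assert abs(np.trace(ens.averaged_lambda_) - 1.0) < 1e-12

    def test_ranking_on_full_sample_not_resample(self, rng):
        X, y = separable_data(rng, gap=1.0)
        ens = BalancedGmlvqEnsemble(n_resamples=6, epochs=40, random_state=2).fit(X, y)
        for m in ens.members_:
            expected = balanced_accuracy_score(y, m.model.predict(X))
            assert m.train_balanced_accuracy == pytest.approx(expected)

    def test_identical_members_tie_resolves_by_index(self, rng):
        X, y = separable_data(rng)
        ens = BalancedGmlvqEnsemble(n_resamples=5, epochs=20, random_state=0).fit(X, y)
        member = ens.members_[0]
        ens.members_ = [
            EnsembleMember(member.model, 0.9, s) for s in range(5)
        ]
        ens.select_top(0.4)
        assert list(np.nonzero(ens.selected_)[0]) == [0, 1]

    def test_full_pipeline_determinism(self, rng):
        X, y = separable_data(rng, gap=1.5)
        kw = dict(n_resamples=6, epochs=40, random_state=3)
        e1 = BalancedGmlvqEnsemble(**kw).fit(X, y)
        e2 = BalancedGmlvqEnsemble(**kw).fit(X, y)
        assert np.array_equal(e1.averaged_lambda_, e2.averaged_lambda_)
        assert np.array_equal(e1.predict(X), e2.predict(X))


def synthetic_member(w_s, w_p, omega=None):
    """Hand-built GMLVQ member with known prototypes."""
    p = len(w_s)
    clf = GmlvqClassifier()
    clf.classes_ = np.asarray(["sMCI", "pMCI"], dtype=object)
    clf._class_codes_ = np.sort(clf.classes_.astype(str))
    clf._order_lookup_ = np.array([1, 0])
    clf.prototypes_ = np.asarray([w_s, w_p], float)
    clf.omega_ = np.eye(p) / np.sqrt(p) if omega is None else np.asarray(omega, float)
    clf.lambda_ = relevance_matrix(clf.omega_)
    clf.cost_trace_ = np.asarray([0.0])
    clf.n_features_in_ = p
    return clf


def hand_ensemble(members):
    ens = BalancedGmlvqEnsemble(n_resamples=len(members))
    ens.members_ = [EnsembleMember(m, 1.0, i) for i, m in enumerate(members)]
    ens.selected_ = np.ones(len(members), dtype=bool)
    ens.selection_fraction_ = 1.0
    ens.classes_ = members[0].classes_
    ens.n_features_in_ = members[0].n_features_in_
    ens.averaged_prototypes_ = np.mean([m.prototypes_ for m in members], axis=0)
    ens.averaged_lambda_ = np.mean([m.lambda_ for m in members], axis=0)
    return ens


class TestVotingAndScore:
    def test_unanimous_and_strict_majority(self):
        left = synthetic_member([0.0, 0.0], [4.0, 0.0])
        right = synthetic_member([4.0, 0.0], [0.0, 0.0])  # votes opposite near 0
        x = np.array([[0.2, 0.0]])
        assert hand_ensemble([left] * 3).predict(x)[0] == "sMCI"
        # 2 of 3 vote pMCI
        assert hand_ensemble([right, right, left]).predict(x)[0] == "pMCI"

    def test_even_split_resolved_by_averaged_model(self):
        left = synthetic_member([0.0, 0.0], [4.0, 0.0])
        right = synthetic_member([4.0, 0.0], [0.0, 0.0])
        ens = hand_ensemble([left, right])
        # averaged prototypes are both (2, 0): degenerate axis, but distances
        # tie exactly, and the residual tie goes progressive
        assert ens.predict(np.array([[1.0, 0.0]]))[0] == "pMCI"

        # non-degenerate averaged tie-break: averaged w_p nearer than w_s
        a = synthetic_member([0.0, 0.0], [4.0, 0.0])
        b = synthetic_member([1.0, 0.0], [3.0, 0.0])
        b2 = synthetic_member([3.0, 0.0], [1.0, 0.0])
        ens2 = hand_ensemble([a, b2])
        d = ens2._averaged_distances(np.array([[2.6, 0.0]]))[0]
        assert d[1] < d[0]
        assert ens2.predict(np.array([[2.6, 0.0]]))[0] == "pMCI"
        del b

    def test_score_limits_and_symmetry(self):
        m = synthetic_member([0.0, 0.0], [4.0, 0.0])
        ens = hand_ensemble([m])
        assert ens.decision_function(np.array([[4.0, 0.0]]))[0] == pytest.approx(1.0)
        assert ens.decision_function(np.array([[2.0, 0.0]]))[0] == pytest.approx(0.0)

    def test_score_sign_agrees_with_vote(self):
        from mciprog import ProgressionModel, SimulationParams, simulate_baseline

        cohort, _ = simulate_baseline(SimulationParams(seed=7))
        model = ProgressionModel(n_resamples=20, random_state=7).fit(cohort)
        ens = model.ensemble_
        X = model._preprocess(cohort)
        votes = ens.predict(X)
        scores = ens.decision_function(X)
        agree = ((scores > 0) == (votes == "pMCI")) | (scores == 0)
        assert agree.mean() >= 0.95

    def test_no_selected_members_is_an_error(self):
        m = synthetic_member([0.0, 0.0], [4.0, 0.0])
        ens = hand_ensemble([m])
        ens.selected_[:] = False
        with pytest.raises(SelectionError):
            ens.predict(np.zeros((1, 2)))


class TestEnsembleBeatsSingleOnImbalance:
    def test_majority_vote_at_least_as_good_on_average(self):
        """Balanced-resample voting vs one model trained on the raw imbalance."""
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_s, n_p = 60, 18
            X = rng.normal(size=(n_s + n_p, 3))
            y = labels(n_s, n_p)
            X[y == "pMCI"] -= np.array([1.2, 0.8, 0.6])
            Xt = rng.normal(size=(200, 3))
            yt = labels(100, 100)
            Xt[yt == "pMCI"] -= np.array([1.2, 0.8, 0.6])

            ens = BalancedGmlvqEnsemble(
                n_resamples=11, epochs=120, random_state=seed
            ).fit(X, y)
            single = train_gmlvq(X, y, GmlvqHyper(epochs=120, seed=seed))
            vote_ba = balanced_accuracy_score(yt, ens.predict(Xt))
            single_ba = balanced_accuracy_score(yt, single.predict(Xt))
            diffs.append(vote_ba - single_ba)
        assert np.mean(diffs) >= 0.0
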