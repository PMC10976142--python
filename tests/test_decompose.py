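import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ephah.decompose import (
    DecompositionClassifier,
    make_plan,
    plan_ephah,
    plan_oaa,
    plan_oao,
    vote_from_responses,
)


def classes(k):
    return [f"C{i}" for i in range(1, k + 1)]


class TestPlanners:
    @pytest.mark.parametrize("k", range(2, 13))
    def test_task_counts_match_combinatorics(self, k):
        cs = classes(k)
        assert plan_oao(cs).n_tasks == k * (k - 1) // 2
        assert plan_oaa(cs).n_tasks == k
        h = (k + 1) // 2
        expected = comb(k, h) // 2 if k % 2 == 0 else comb(k, h)
        assert plan_ephah(cs).n_tasks == expected

    def test_ten_class_reference_counts(self):
        cs = classes(10)
        assert plan_oao(cs).n_tasks == 45
        assert plan_oaa(cs).n_tasks == 10
        assert plan_ephah(cs).n_tasks == 126
        assert plan_ephah(classes(6)).n_tasks == 10

    def test_oao_enumerates_all_pairs(self):
        plan = plan_oao(classes(5))
        pairs = {(t.positive_group[0], t.negative_group[0])
                 for t in plan.tasks}
        expected = {(f"C{i}", f"C{j}")
                    for i, j in itertools.combinations(range(1, 6), 2)}
        assert pairs == expected

    def test_oaa_groups_partition_class_set(self):
        plan = plan_oaa(classes(6))
        for t in plan.tasks:
            assert len(t.positive_group) == 1
            assert set(t.members) == set(classes(6))

    def test_ephah_three_class_enumeration(self):
        plan = plan_ephah(classes(3))
        got = {(frozenset(t.positive_group), frozenset(t.negative_group))
               for t in plan.tasks}
        assert got == {
            (frozenset({"C1", "C2"}), frozenset({"C3"})),
            (frozenset({"C1", "C3"}), frozenset({"C2"})),
            (frozenset({"C2", "C3"}), frozenset({"C1"})),
        }

    @given(k=st.integers(2, 12))
    @settings(deadline=None, max_examples=11)
    def test_ephah_no_duplicate_or_complement_tasks(self, k):
        plan = plan_ephah(classes(k))
        seen = set()
        for t in plan.tasks:
            key = frozenset({frozenset(t.positive_group),
                             frozenset(t.negative_group)})
            assert key not in seen
            seen.add(key)
            assert set(t.members) == set(classes(k))
            # balanced halves
            assert len(t.positive_group) - len(t.negative_group) in (0, 1)

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            plan_oao(["only"])
        with pytest.raises(ValueError):
            make_plan("unknown", classes(3))


class TestVoting:
    def test_six_class_unanimous_oracle_tally(self):
        # every binary decision favors the side containing class C1
        plan = plan_ephah(classes(6))
        resp = np.array([[1.0 if "C1" in t.positive_group else -1.0
                          for t in plan.tasks]])
        votes = vote_from_responses(plan, resp)
        assert votes[0].tolist() == [10, 4, 4, 4, 4, 4]
        assert plan.classes[int(np.argmax(votes[0]))] == "C1"

    def test_two_class_reduces_to_sign_decision(self):
        plan = plan_ephah(classes(2))
        assert plan.n_tasks == 1
        up = vote_from_responses(plan, np.array([[0.3]]))
        down = vote_from_responses(plan, np.array([[-0.3]]))
        assert up[0].tolist() == [1, 0]
        assert down[0].tolist() == [0, 1]

    @pytest.mark.parametrize("strategy", ["oao", "ephah"])
    def test_tallies_match_direct_rule_evaluation(self, strategy, rng):
        plan = make_plan(strategy, classes(4))
        resp = rng.normal(size=(20, plan.n_tasks))
        votes = vote_from_responses(plan, resp, threshold_c=0.0)
        # direct per-definition evaluation: response ≥ c votes for every
        # positive-group class, otherwise for every negative-group class
        for s in range(20):
            tally = dict.fromkeys(plan.classes, 0)
            for t, task in enumerate(plan.tasks):
                group = (task.positive_group if resp[s, t] >= 0
                         else task.negative_group)
                for c in group:
                    tally[c] += 1
            assert votes[s].tolist() == [tally[c] for c in plan.classes]

    def test_response_shape_mismatch_rejected(self):
        plan = plan_oao(classes(3))
        with pytest.raises(ValueError):
            vote_from_responses(plan, np.zeros((2, 99)))


def separable_problem(rng, k=3, per=12, m=20, gap=6.0):
    centers = rng.normal(scale=gap, size=(k, m))
    X = np.vstack([centers[c] + rng.normal(size=(per, m))
                   for c in range(k)])
    y = np.array([f"C{c + 1}" for c in range(k) for _ in range(per)])
    return X, y


class TestClassifier:
    @pytest.mark.parametrize("strategy", ["oao", "oaa", "ephah"])
    def test_separable_training_accuracy_is_one(self, strategy, rng):
        X, y = separable_problem(rng)
        clf = DecompositionClassifier(strategy=strategy, max_lv=4,
                                      mccv_splits=8).fit(X, y)
        assert clf.score(X, y) == 1.0

    def test_ephah_k4_uses_three_tasks_trained_on_all(self, rng):
        X, y = separable_problem(rng, k=4)
        clf = DecompositionClassifier(strategy="ephah", max_lv=3,
                                      mccv_splits=8).fit(X, y)
        assert clf.plan_.n_tasks == 3
        for task in clf.plan_.tasks:
            assert set(task.members) == set(clf.classes_)

    def test_mean_lv_is_arithmetic_mean(self, rng):
        X, y = separable_problem(rng, k=3)
        clf = DecompositionClassifier(strategy="oao", max_lv=4,
                                      mccv_splits=8).fit(X, y)
        assert clf.lv_mean_ == pytest.approx(np.mean(clf.lv_per_task_))

    def test_classes_in_first_appearance_order(self, rng):
        X, y = separable_problem(rng, k=3)
        order = np.argsort(y, kind="stable")[::-1]
        clf = DecompositionClassifier(strategy="oao", max_lv=2,
                                      mccv_splits=8).fit(X[order], y[order])
        assert clf.classes_.tolist() == ["C3", "C2", "C1"]

    @pytest.mark.parametrize("strategy", ["oao", "oaa", "ephah"])
    def test_permutation_equivariance_under_relabeling(self, strategy, rng):
        X, y = separable_problem(rng, k=3, per=10)
        Xte = X + 0.1 * rng.normal(size=X.shape)
        clf = DecompositionClassifier(strategy=strategy, max_lv=3,
                                      mccv_splits=8, random_state=1).fit(X, y)
        pred = clf.predict(Xte)
        # rename classes with a permutation; predictions must rename too
        rename = {"C1": "Z", "C2": "Q", "C3": "A"}
        y2 = np.array([rename[v] for v in y])
        clf2 = DecompositionClassifier(strategy=strategy, max_lv=3,
                                       mccv_splits=8, random_state=1).fit(X, y2)
        pred2 = clf2.predict(Xte)
        assert [rename[v] for v in pred] == list(pred2)

    def test_vote_matrix_shape_and_winner_consistency(self, rng):
        X, y = separable_problem(rng, k=3)
        clf = DecompositionClassifier(strategy="ephah", max_lv=3,
                                      mccv_splits=8).fit(X, y)
        votes, winners = clf.vote(X[:5])
        assert votes.shape == (5, 3)
        for v, w in zip(votes, winners):
            top = {clf.classes_[i] for i in np.flatnonzero(v == v.max())}
            assert w in top


class TestTieResolution:
    def test_no_tie_returns_vote_winner(self, rng):
        X, y = separable_problem(rng, k=3, gap=8.0)
        clf = DecompositionClassifier(strategy="ephah", max_lv=3,
                                      mccv_splits=8).fit(X, y)
        votes, winners = clf.vote(X)
        clear = [i for i, v in enumerate(votes)
                 if (v == v.max()).sum() == 1]
        assert clear  # separable data has mostly clear votes
        for i in clear[:10]:
            assert winners[i] == clf.classes_[int(np.argmax(votes[i]))]

    def test_two_way_tie_resolved_by_sub_model(self, rng):
        X, y = separable_problem(rng, k=2, per=15)
        clf = DecompositionClassifier(strategy="ephah", max_lv=3,
                                      mccv_splits=8).fit(X, y)
        # direct call: a 2-class tie resolves deterministically to one of them
        winner = clf.resolve_ties(("C1", "C2"), X[0], depth=2)
        assert winner in ("C1", "C2")
        again = clf.resolve_ties(("C1", "C2"), X[0], depth=2)
        assert winner == again

    def test_symmetric_tie_is_deterministic_across_runs(self, rng):
        X, y = separable_problem(rng, k=4, per=10)
        mk = lambda: DecompositionClassifier(strategy="oao", max_lv=2,
                                             mccv_splits=8,
                                             random_state=3).fit(X, y)
        a, b = mk(), mk()
        x = X.mean(axis=0)  # equidistant-ish probe point
        w1 = a.resolve_ties(("C1", "C2", "C3"), x, depth=2)
        w2 = b.resolve_ties(("C1", "C2", "C3"), x, depth=2)
        assert w1 == w2
        # depth 0 falls back to the margin rule, still deterministic
        assert (a.resolve_ties(("C1", "C2", "C3"), x, depth=0)
                == b.resolve_ties(("C1", "C2", "C3"), x, depth=0))
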