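"""Multiclass decomposition of PLS-DA: OAO, OAA, and EPHAH strategies.

A k-class problem is decomposed into parallel binary tasks, each solved by
a binary PLS-DA model on a ±1 coded response:

* **OAO** (one-against-one): one task per unordered class pair — k(k−1)/2
  models, each trained only on its two classes.  Each model votes for one
  of its classes; the class with the most votes wins.
* **OAA** (one-against-all): k models, class i (+1) versus the rest (−1),
  each trained on all samples.  Prediction is the argmax of the k
  continuous responses (no vote thresholding).
* **EPHAH** (exhaustive parallel half-against-half): every balanced
  bipartition of the class set is a task.  For even k there are
  C(k, k/2)/2 distinct tasks (complementary bipartitions coincide); for
  odd k the positive group has ⌈k/2⌉ classes and there are C(k, ⌈k/2⌉)
  tasks.  Every model is trained on all samples, so the two sides are
  nearly balanced.  A model whose response clears the threshold casts one
  vote for *every* class on its positive side, otherwise for every class
  on its negative side; maximum-win voting over all tasks decides.

Because each EPHAH vote carries information about all k classes, the true
class can collect every vote while each wrong class shares only the tasks
that placed it alongside the truth — for k=6 the clean tally is
(10, 4, 4, 4, 4, 4).  Vote ties are resolved by a recursive sub-
decomposition restricted to the tied classes, falling back to the largest
mean response margin (then class order) at the depth limit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .pls import PLSDABinary, mccv_select_lvs

__all__ = [
    "ClassPartition",
    "DecompositionPlan",
    "DecompositionClassifier",
    "plan_oao",
    "plan_oaa",
    "plan_ephah",
    "make_plan",
    "vote_from_responses",
]

STRATEGIES = ("oao", "oaa", "ephah")


@dataclass(frozen=True)
class ClassPartition:
    """One binary task: positive class group G_P versus negative group G_N."""

    positive_group: tuple[str, ...]
    negative_group: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.positive_group or not self.negative_group:
            raise ValueError("both groups must be non-empty")
        if set(self.positive_group) & set(self.negative_group):
            raise ValueError("groups must be disjoint")

    @property
    def members(self) -> tuple[str, ...]:
        return self.positive_group + self.negative_group


@dataclass(frozen=True)
class DecompositionPlan:
    """Ordered binary task list for one strategy over an ordered class set."""

    strategy: str
    classes: tuple[str, ...]
    tasks: tuple[ClassPartition, ...]

    @property
    def k(self) -> int:
        return len(self.classes)

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)


def _check_k(classes) -> tuple[str, ...]:
    classes = tuple(str(c) for c in classes)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if len(set(classes)) != len(classes):
        raise ValueError("duplicate class names")
    return classes


def plan_oao(classes) -> DecompositionPlan:
    """All unordered pairs (i < j), i positive, lexicographic by index."""
    classes = _check_k(classes)
    tasks = tuple(
        ClassPartition((classes[i],), (classes[j],))
        for i, j in itertools.combinations(range(len(classes)), 2)
    )
    return DecompositionPlan("oao", classes, tasks)


def plan_oaa(classes) -> DecompositionPlan:
    """Task i: class i against all others, in class order."""
    classes = _check_k(classes)
    tasks = tuple(
        ClassPartition((c,), tuple(o for o in classes if o != c))
        for c in classes
    )
    return DecompositionPlan("oaa", classes, tasks)


def plan_ephah(classes) -> DecompositionPlan:
    """All balanced class bipartitions, complements deduplicated for even k.

    Even k: the ⌈k/2⌉-subsets containing the first class (each bipartition
    appears once) — C(k, k/2)/2 tasks.  Odd k: all ⌈k/2⌉-subsets as the
    positive group — C(k, ⌈k/2⌉) tasks.  Lexicographic index order.
    """
    classes = _check_k(classes)
    k = len(classes)
    h = (k + 1) // 2
    idx = range(k)
    if k % 2 == 0:
        combos = [(0, *rest) for rest in itertools.combinations(range(1, k), h - 1)]
    else:
        combos = list(itertools.combinations(idx, h))
    tasks = []
    for pos in combos:
        pos_set = set(pos)
        tasks.append(ClassPartition(
            tuple(classes[i] for i in pos),
            tuple(classes[i] for i in idx if i not in pos_set),
        ))
    return DecompositionPlan("ephah", classes, tuple(tasks))


def make_plan(strategy: str, classes) -> DecompositionPlan:
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")
    return {"oao": plan_oao, "oaa": plan_oaa, "ephah": plan_ephah}[strategy](classes)


def vote_from_responses(
    plan: DecompositionPlan, responses: np.ndarray, threshold_c: float = 0.0
) -> np.ndarray:
    """Binary vote matrix (n_samples × k) from per-task continuous responses.

    A task response ≥ threshold casts votes for the positive group (one per
    member), otherwise for the negative group; for OAO groups are
    singletons, so this reduces to pairwise voting.
    """
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    n, T = responses.shape
    if T != plan.n_tasks:
        raise ValueError(f"{T} response columns for {plan.n_tasks} tasks")
    pos_map = {c: i for i, c in enumerate(plan.classes)}
    votes = np.zeros((n, plan.k), dtype=int)
    for t, task in enumerate(plan.tasks):
        up = responses[:, t] >= threshold_c
        pos_idx = [pos_map[c] for c in task.positive_group]
        neg_idx = [pos_map[c] for c in task.negative_group]
        votes[np.ix_(up, pos_idx)] += 1
        votes[np.ix_(~up, neg_idx)] += 1
    return votes


class DecompositionClassifier(BaseEstimator, ClassifierMixin):
    """Multiclass classifier from binary PLS-DA models under a decomposition.

    Parameters
    ----------
    strategy : {"oao", "oaa", "ephah"}
    threshold_c : float
        Decision threshold on the ±1 coded response (0 by default).
    max_lv : int
        Upper bound of the latent-variable search.
    mccv_splits : int
        Monte Carlo CV splits per task for LV selection.
    holdout_fraction : float
        MCCV holdout fraction.
    tie_depth : int
        Recursion depth for vote-tie resolution by sub-decomposition.
    random_state : int
        Seeds the MCCV splits.

    Fitted attributes
    -----------------
    classes_ : class names in first-appearance order
    plan_ : the decomposition plan
    models_ : one fitted :class:`PLSDABinary` per task
    lv_per_task_, lv_mean_ : chosen LV counts and their mean
    ermccv_per_task_, ermccv_mean_ : per-task chosen MCCV error rates
    """

    def __init__(self, strategy: str = "ephah", threshold_c: float = 0.0,
                 max_lv: int = 10, mccv_splits: int = 20,
                 holdout_fraction: float = 0.2, tie_depth: int = 2,
                 random_state: int = 0):
        self.strategy = strategy
        self.threshold_c = threshold_c
        self.max_lv = max_lv
        self.mccv_splits = mccv_splits
        self.holdout_fraction = holdout_fraction
        self.tie_depth = tie_depth
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray([str(v) for v in np.asarray(y).ravel()])
        if X.shape[0] != y.size:
            raise ValueError("X and y sizes disagree")
        classes = list(dict.fromkeys(y.tolist()))  # first-appearance order
        self.classes_ = np.asarray(classes)
        self.plan_ = make_plan(self.strategy, classes)
        self.models_ = []
        self.lv_per_task_ = []
        self.ermccv_per_task_ = []
        for t, task in enumerate(self.plan_.tasks):
            mask = np.isin(y, task.members)
            Xt, yt = X[mask], y[mask]
            coded = np.where(np.isin(yt, task.positive_group), 1.0, -1.0)
            if np.unique(coded).size < 2:
                raise ValueError(f"task {t}: a class group has no samples")
            n_lv, err = self._select_lv(Xt, coded, seed_offset=t)
            model = PLSDABinary(n_components=n_lv,
                                threshold_c=self.threshold_c).fit(Xt, coded)
            self.models_.append(model)
            self.lv_per_task_.append(n_lv)
            self.ermccv_per_task_.append(err)
        self.lv_mean_ = float(np.mean(self.lv_per_task_))
        self.ermccv_mean_ = float(np.mean(self.ermccv_per_task_))
        self._X_train, self._y_train = X, y
        self._tie_cache: dict[tuple[str, ...], DecompositionClassifier] = {}
        return self

    def _select_lv(self, Xt, coded, seed_offset: int) -> tuple[int, float]:
        max_lv = max(1, min(self.max_lv, Xt.shape[0] - 2, Xt.shape[1]))
        res = mccv_select_lvs(
            Xt, coded, max_lv=max_lv, n_splits=self.mccv_splits,
            holdout_fraction=self.holdout_fraction,
            seed=(self.random_state * 1009 + seed_offset) % (2**31),
            threshold_c=self.threshold_c,
        )
        return res.chosen_n_lv, res.chosen_error_rate

    # -- prediction --------------------------------------------------------

    def decision_responses(self, X) -> np.ndarray:
        """Continuous per-task responses, shape (n_samples, n_tasks)."""
        X = np.asarray(X, dtype=float)
        return np.column_stack([m.decision_function(X) + self.threshold_c
                                for m in self.models_])

    def vote(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Vote matrix and predicted classes (ties resolved)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        responses = self.decision_responses(X)
        if self.strategy == "oaa":
            votes = responses  # score vector; argmax rule
            winners = self.classes_[np.argmax(responses, axis=1)]
            return votes, winners
        votes = vote_from_responses(self.plan_, responses, self.threshold_c)
        winners = np.empty(X.shape[0], dtype=self.classes_.dtype)
        for i in range(X.shape[0]):
            v = votes[i]
            top = np.flatnonzero(v == v.max())
            if top.size == 1:
                winners[i] = self.classes_[top[0]]
            else:
                tied = tuple(self.classes_[top])
                winners[i] = self.resolve_ties(tied, X[i], self.tie_depth,
                                               responses[i])
        return votes, winners

    def predict(self, X):
        _, winners = self.vote(X)
        return winners

    def resolve_ties(self, tied_classes: tuple[str, ...], x_row: np.ndarray,
                     depth: int, responses: np.ndarray | None = None) -> str:
        """Resolve a vote tie among ``tied_classes`` for one sample.

        A sub-decomposition restricted to the tied classes (same strategy,
        lazily trained and cached) re-votes; at depth 0 or if the sub-model
        cannot shrink the tie, the class with the largest mean response
        margin wins, class order breaking any remaining tie.
        """
        tied = tuple(tied_classes)
        if len(tied) < 2:
            return tied[0]
        if depth > 0 and len(tied) < len(self.classes_):
            sub = self._tie_cache.get(tied)
            if sub is None:
                mask = np.isin(self._y_train, tied)
                sub = DecompositionClassifier(
                    strategy=self.strategy, threshold_c=self.threshold_c,
                    max_lv=self.max_lv, mccv_splits=self.mccv_splits,
                    holdout_fraction=self.holdout_fraction,
                    tie_depth=depth - 1, random_state=self.random_state + 1,
                ).fit(self._X_train[mask], self._y_train[mask])
                self._tie_cache[tied] = sub
            return str(sub.predict(x_row[None, :])[0])
        # margin fallback
        if responses is None:
            responses = self.decision_responses(x_row[None, :])[0]
        margins = self._mean_margins(responses)
        order = {c: i for i, c in enumerate(self.classes_)}
        best = max(tied, key=lambda c: (margins[c], -order[c]))
        return best

    def _mean_margins(self, responses: np.ndarray) -> dict[str, float]:
        """Per-class mean signed response over the tasks involving it."""
        sums: dict[str, float] = {c: 0.0 for c in self.classes_}
        counts: dict[str, int] = {c: 0 for c in self.classes_}
        for t, task in enumerate(self.plan_.tasks):
            r = float(responses[t]) - self.threshold_c
            for c in task.positive_group:
                sums[c] += r
                counts[c] += 1
            for c in task.negative_group:
                sums[c] -= r
                counts[c] += 1
        return {c: (sums[c] / counts[c] if counts[c] else 0.0)
                for c in self.classes_}

    def score(self, X, y):
        y = np.asarray([str(v) for v in np.asarray(y).ravel()])
        return float(np.mean(self.predict(X) == y))

    def confusion_matrix(self, X, y) -> np.ndarray:
        """Rows = true class (in ``classes_`` order), columns = predicted."""
        y = np.asarray([str(v) for v in np.asarray(y).ravel()])
        pred = self.predict(X)
        pos = {c: i for i, c in enumerate(self.classes_)}
        cm = np.zeros((len(self.classes_), len(self.classes_)), dtype=int)
        for t, p in zip(y, pred):
            cm[pos[t], pos[p]] += 1
        return cm
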