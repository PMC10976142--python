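"""Representative sample-set partitioning: Kennard–Stone, SPXY, DUPLEX, random.

All methods are deterministic given their inputs (ties broken by lowest
sample index); the random split is fully seeded.  Stratified ratio splits
use per-class rounding rules documented on each function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .spectra import SpectraSet

__all__ = [
    "SplitResult",
    "kennard_stone",
    "spxy_split",
    "duplex_stratified",
    "random_split",
]


@dataclass
class SplitResult:
    """Disjoint train/val/test id lists covering the full sample set."""

    train_ids: list[str]
    test_ids: list[str]
    val_ids: list[str] = field(default_factory=list)
    method: str = ""
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        parts = [self.train_ids, self.val_ids, self.test_ids]
        flat = [s for p in parts for s in p]
        if len(flat) != len(set(flat)):
            raise ValueError("split sets overlap or contain duplicates")

    @property
    def all_ids(self) -> set[str]:
        return set(self.train_ids) | set(self.val_ids) | set(self.test_ids)


def _maxmin_selection(D: np.ndarray, n_select: int) -> list[int]:
    """Classic Kennard–Stone on a precomputed distance matrix.

    Starts from the mutually farthest pair, then repeatedly adds the sample
    with the largest minimum distance to the selected set.  Ties go to the
    lowest index.
    """
    n = D.shape[0]
    if not 2 <= n_select <= n:
        raise ValueError(f"n_select must be in [2, {n}]")
    # farthest pair; argmax of the flattened matrix is the lowest-index tie
    i, j = np.unravel_index(int(np.argmax(D)), D.shape)
    selected = [min(i, j), max(i, j)]
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    mask = np.ones(n, dtype=bool)
    mask[selected] = False
    while len(selected) < n_select:
        cand = np.where(mask, min_dist, -np.inf)
        nxt = int(np.argmax(cand))
        selected.append(nxt)
        mask[nxt] = False
        min_dist = np.minimum(min_dist, D[nxt])
    return selected


def kennard_stone(s: SpectraSet | np.ndarray, n_select: int) -> list:
    """Kennard–Stone max–min selection; returns sample ids (or row indices)."""
    if isinstance(s, SpectraSet):
        D = cdist(s.absorbance, s.absorbance)
        idx = _maxmin_selection(D, n_select)
        return [s.sample_ids[i] for i in idx]
    X = np.asarray(s, float)
    return _maxmin_selection(cdist(X, X), n_select)


def _joint_distance(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """SPXY distance: x- and y-distances each normalized by their maximum."""
    Dx = cdist(X, X)
    if y.ndim == 1:
        y = y[:, None]
    Dy = cdist(y, y)
    mx = Dx.max()
    if mx == 0:
        raise ValueError("all spectra identical: SPXY distance degenerate")
    my = Dy.max()
    return Dx / mx + (Dy / my if my > 0 else 0.0)


def _one_hot(labels: Sequence) -> np.ndarray:
    classes = list(dict.fromkeys(labels))
    pos = {c: k for k, c in enumerate(classes)}
    out = np.zeros((len(labels), len(classes)))
    for i, l in enumerate(labels):
        out[i, pos[l]] = 1.0
    return out


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


def spxy_split(
    s: SpectraSet,
    y: Sequence | np.ndarray | None = None,
    train_fraction: float = 0.7,
    stratify: bool | None = None,
) -> SplitResult:
    """SPXY partition: Kennard–Stone on the joint spectral+response distance.

    Class labels are one-hot encoded for the response distance.  With
    ``stratify`` (default when labels are present) selection runs per class
    with round-half-even train counts; otherwise globally.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if y is None:
        if s.labels is None:
            raise ValueError("provide y or a labeled SpectraSet")
        y = s.labels
    y = np.asarray(y)
    if stratify is None:
        stratify = y.dtype.kind in ("U", "S", "O")
    yv = _one_hot(y) if y.dtype.kind in ("U", "S", "O") else y.astype(float)

    train_idx: list[int] = []
    if stratify:
        for c in dict.fromkeys(y.tolist()):
            idx = np.flatnonzero(y == c)
            n_tr = _round_half_even(train_fraction * len(idx))
            n_tr = max(2, min(n_tr, len(idx)))
            D = _joint_distance(s.absorbance[idx], yv[idx])
            picked = _maxmin_selection(D, n_tr)
            train_idx.extend(int(idx[i]) for i in picked)
    else:
        D = _joint_distance(s.absorbance, yv)
        n_tr = max(2, _round_half_even(train_fraction * s.n_samples))
        train_idx = _maxmin_selection(D, n_tr)

    train_set = set(train_idx)
    test_idx = [i for i in range(s.n_samples) if i not in train_set]
    return SplitResult(
        train_ids=[s.sample_ids[i] for i in sorted(train_set)],
        test_ids=[s.sample_ids[i] for i in test_idx],
        method="spxy",
        params={"train_fraction": train_fraction, "stratify": stratify},
    )


def stratified_622_counts(n_c: int, ratios: tuple[float, float, float]
                          ) -> tuple[int, int, int]:
    """Per-class counts under the floor/even-remainder rule.

    Train gets ``floor(train_ratio·n)``; the remainder splits equally
    between validation and test, an odd remainder giving the extra sample
    to validation.
    """
    n_train = int(np.floor(ratios[0] * n_c))
    rem = n_c - n_train
    n_val = (rem + 1) // 2
    n_test = rem - n_val
    return n_train, n_val, n_test


def duplex_stratified(
    s: SpectraSet, ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
) -> SplitResult:
    """Stratified DUPLEX train/validation/test partition.

    Per class, counts follow :func:`stratified_622_counts`; assignment uses
    DUPLEX-style alternation on Euclidean distances: each set is seeded with
    the farthest remaining pair, then sets take turns (train, val, test)
    picking the remaining sample farthest (max–min) from their current
    members until their quota is filled.
    """
    if s.labels is None:
        raise ValueError("stratified DUPLEX requires labels")
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be positive and sum to 1")
    lab = np.asarray(s.labels)
    sets: tuple[list[str], list[str], list[str]] = ([], [], [])
    for c in s.class_order():
        idx = np.flatnonzero(lab == c)
        if len(idx) < 3:
            raise ValueError(f"class {c!r} has fewer than 3 samples")
        quotas = stratified_622_counts(len(idx), ratios)
        D = cdist(s.absorbance[idx], s.absorbance[idx])
        assigned = _duplex_assign(D, quotas)
        for k in range(3):
            sets[k].extend(s.sample_ids[idx[i]] for i in assigned[k])
    return SplitResult(
        train_ids=sets[0], val_ids=sets[1], test_ids=sets[2],
        method="duplex", params={"ratios": ratios},
    )


def _duplex_assign(D: np.ndarray, quotas: tuple[int, int, int]
                   ) -> tuple[list[int], list[int], list[int]]:
    n = D.shape[0]
    remaining = set(range(n))
    members: list[list[int]] = [[], [], []]

    def farthest_pair() -> tuple[int, int]:
        rem = sorted(remaining)
        sub = D[np.ix_(rem, rem)]
        i, j = np.unravel_index(int(np.argmax(sub)), sub.shape)
        return rem[min(i, j)], rem[max(i, j)]

    # seed each set with the farthest remaining pair (respecting quota)
    for k in range(3):
        take = min(2, quotas[k], len(remaining))
        if take == 2:
            a, b = farthest_pair()
            members[k] += [a, b]
            remaining -= {a, b}
        elif take == 1:
            a = min(remaining)
            members[k].append(a)
            remaining.discard(a)

    # alternate: each set in turn takes its max-min-distance sample
    while remaining:
        progressed = False
        for k in range(3):
            if len(members[k]) >= quotas[k] or not remaining:
                continue
            rem = sorted(remaining)
            dmin = D[np.ix_(rem, members[k])].min(axis=1)
            pick = rem[int(np.argmax(dmin))]
            members[k].append(pick)
            remaining.discard(pick)
            progressed = True
        if not progressed:  # all quotas filled but samples remain (cannot happen)
            members[0].extend(sorted(remaining))
            break
    return members[0], members[1], members[2]


def random_split(
    s: SpectraSet,
    fractions: tuple[float, ...] = (0.7, 0.0, 0.3),
    seed: int = 0,
) -> SplitResult:
    """Seeded uniform split, stratified by label when labels are present.

    ``fractions`` is (train, val, test) and must sum to 1; per-group counts
    round by largest remainder so the partition is exact.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    sets: tuple[list[str], list[str], list[str]] = ([], [], [])

    def cut(idx: np.ndarray) -> None:
        idx = rng.permutation(idx)
        n = len(idx)
        counts = _largest_remainder(n, fractions)
        start = 0
        for k, c in enumerate(counts):
            sets[k].extend(s.sample_ids[i] for i in idx[start:start + c])
            start += c

    if s.labels is not None:
        lab = np.asarray(s.labels)
        for c in s.class_order():
            cut(np.flatnonzero(lab == c))
    else:
        cut(np.arange(s.n_samples))
    return SplitResult(
        train_ids=sets[0], val_ids=sets[1], test_ids=sets[2],
        method="random", params={"fractions": fractions}, seed=seed,
    )


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [f * n for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    short = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])  # largest remainder first
    for k in order[:short]:
        base[k] += 1
    return base
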