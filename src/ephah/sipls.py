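"""Synergy-interval PLS: exhaustive j-of-k interval search by RMSECV.

The wavenumber axis is divided into k contiguous equal-width intervals;
every combination of j intervals is scored by the cross-validated RMSE of
a PLS model restricted to those columns, and the minimizing combination is
the selected characteristic region.  Across the binary models of a
multiclass decomposition, the per-interval selection frequency highlights
chemically meaningful spectral regions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np

from .pls import rmsecv_curve
from .spectra import WavenumberGrid

__all__ = [
    "IntervalGrid",
    "SIPLSResult",
    "FrequencyTable",
    "divide_intervals",
    "sipls_search",
    "selection_frequency",
    "top_share",
]


@dataclass(frozen=True)
class IntervalGrid:
    """k contiguous equal-width wavenumber intervals covering the grid.

    Bounds are half-open [lo, hi) except the last interval, which is closed
    at the top so every grid point belongs to exactly one interval.
    """

    k_intervals: int
    bounds: tuple[tuple[float, float], ...]
    width: float
    point_interval: tuple[int, ...]   # interval index of each grid point

    def point_indices(self, interval: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.point_interval) == interval)

    def columns(self, combo: tuple[int, ...]) -> np.ndarray:
        pi = np.asarray(self.point_interval)
        return np.flatnonzero(np.isin(pi, combo))


def divide_intervals(grid: WavenumberGrid, k_intervals: int) -> IntervalGrid:
    """Divide a wavenumber grid into k equal-width (cm⁻¹) intervals.

    The axis extent counts one step-width cell per point, so the width is
    ``n_points·step / k``; points are assigned by half-open membership.
    """
    if not 1 <= k_intervals <= grid.n_points:
        raise ValueError(f"k_intervals must be in [1, {grid.n_points}]")
    lo = grid.start
    span = grid.span
    width = span / k_intervals
    bounds = tuple(
        (lo + i * width, lo + (i + 1) * width) for i in range(k_intervals)
    )
    idx = np.floor((grid.values - lo) / width).astype(int)
    idx = np.clip(idx, 0, k_intervals - 1)
    return IntervalGrid(k_intervals=k_intervals, bounds=bounds, width=width,
                        point_interval=tuple(int(i) for i in idx))


@dataclass
class SIPLSResult:
    """Outcome of one exhaustive synergy-interval search."""

    grid: IntervalGrid
    j: int
    best_combo: tuple[int, ...]
    best_rmsecv: float
    best_n_lv: int
    all_combos_evaluated: int
    scores: dict[tuple[int, ...], float] | None = None


def sipls_search(
    X,
    y,
    interval_grid: IntervalGrid,
    j: int,
    lv_max: int = 10,
    n_folds: int = 5,
    seed: int = 0,
    budget: int = 10**6,
    keep_scores: bool = False,
) -> SIPLSResult:
    """Exhaustively evaluate all C(k, j) interval combinations.

    Per combination, a PLS model on the concatenated interval columns is
    scored by RMSECV at its best LV count ≤ ``lv_max``; the argmin wins,
    lexicographically-first on ties.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    k = interval_grid.k_intervals
    if not 1 <= j <= k:
        raise ValueError(f"j must be in [1, {k}]")
    n_combos = comb(k, j)
    if n_combos > budget:
        raise ValueError(
            f"C({k},{j}) = {n_combos} exceeds the budget of {budget} model "
            "fits; reduce j or k_intervals"
        )
    best: tuple[float, tuple[int, ...], int] | None = None
    scores: dict[tuple[int, ...], float] = {}
    count = 0
    for combo in itertools.combinations(range(k), j):
        cols = interval_grid.columns(combo)
        a = max(1, min(lv_max, len(cols), X.shape[0] - 2))
        curve = rmsecv_curve(X[:, cols], y, max_lv=a, n_folds=n_folds, seed=seed)
        n_lv = int(np.argmin(curve)) + 1
        val = float(curve[n_lv - 1])
        if keep_scores:
            scores[combo] = val
        if best is None or val < best[0]:
            best = (val, combo, n_lv)
        count += 1
    assert best is not None
    return SIPLSResult(
        grid=interval_grid, j=j, best_combo=best[1], best_rmsecv=best[0],
        best_n_lv=best[2], all_combos_evaluated=count,
        scores=scores if keep_scores else None,
    )


@dataclass
class FrequencyTable:
    """Interval selection counts across a collection of fitted searches."""

    counts: np.ndarray          # per interval
    total_selections: int       # n_models × j

    @property
    def relative_frequency(self) -> np.ndarray:
        return self.counts / self.total_selections

    def top_share(self, top: int = 5) -> float:
        return top_share(self.counts, self.total_selections, top)


def top_share(counts, total_selections: int, top: int = 5) -> float:
    """Fraction of all selections captured by the ``top`` most-chosen intervals."""
    counts = np.sort(np.asarray(counts, dtype=float))[::-1]
    return float(counts[:top].sum() / total_selections)


def selection_frequency(results: list[SIPLSResult]) -> FrequencyTable:
    """Count interval membership in ``best_combo`` across searches."""
    if not results:
        raise ValueError("no results")
    g0 = results[0].grid
    j0 = results[0].j
    for r in results[1:]:
        if r.grid != g0 or r.j != j0:
            raise ValueError("all results must share one interval grid and j")
    counts = np.zeros(g0.k_intervals, dtype=int)
    for r in results:
        for i in r.best_combo:
            counts[i] += 1
    return FrequencyTable(counts=counts, total_selections=len(results) * j0)
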