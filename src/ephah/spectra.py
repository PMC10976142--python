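"""Data model and I/O for labeled NIR spectra on a uniform wavenumber grid.

Spectra are stored as an (n_samples, n_points) absorbance matrix over a
strictly increasing, uniformly spaced wavenumber axis in cm⁻¹.  The default
axis convention mirrors a Fourier-transform NIR diffuse-reflectance
acquisition: 4000 cm⁻¹ start, 3.857 cm⁻¹ point spacing, 2074 points
(≈ 4000–12,000 cm⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberGrid",
    "SpectraSet",
    "DEFAULT_GRID",
    "read_spectra",
    "write_spectra",
    "mean_spectrum",
]

#: relative tolerance on grid spacing uniformity when reading files
GRID_RTOL = 1e-3


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform wavenumber axis: point i sits at ``start + i * step`` cm⁻¹."""

    start: float
    step: float
    n_points: int

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        if self.n_points < 2:
            raise ValueError("grid needs at least 2 points")

    @property
    def values(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)

    @property
    def span(self) -> float:
        """Total axis extent in cm⁻¹, counting one step-width cell per point."""
        return self.step * self.n_points

    @classmethod
    def from_values(cls, values: np.ndarray, rtol: float = GRID_RTOL) -> "WavenumberGrid":
        values = np.asarray(values, dtype=float)
        if values.size < 2:
            raise ValueError("grid needs at least 2 points")
        diffs = np.diff(values)
        step = float(np.mean(diffs))
        if step <= 0:
            raise ValueError("grid must be strictly increasing")
        if np.any(np.abs(diffs - step) > rtol * abs(step)):
            raise ValueError("non-uniform grid")
        return cls(start=float(values[0]), step=step, n_points=values.size)


#: the package-wide default acquisition grid
DEFAULT_GRID = WavenumberGrid(start=4000.0, step=3.857, n_points=2074)


@dataclass
class SpectraSet:
    """A labeled collection of spectra sharing one wavenumber grid.

    Parameters
    ----------
    grid : WavenumberGrid
        Shared wavenumber axis.
    absorbance : ndarray of shape (n_samples, n_points)
        Absorbance values.
    sample_ids : sequence of str
        Unique per-row identifiers.
    labels : sequence of str, optional
        Class name per sample.  Class order for reports is first-appearance
        order.
    """

    grid: WavenumberGrid
    absorbance: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        n, m = self.absorbance.shape
        if m != self.grid.n_points:
            raise ValueError(
                f"absorbance has {m} columns but grid has {self.grid.n_points} points"
            )
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n:
            raise ValueError("one sample_id per row required")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if self.labels is not None:
            self.labels = [str(l) for l in self.labels]
            if len(self.labels) != n:
                raise ValueError("one label per sample required")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    def class_order(self) -> list[str]:
        """Distinct labels in first-appearance order."""
        if self.labels is None:
            return []
        seen: dict[str, None] = {}
        for l in self.labels:
            seen.setdefault(l)
        return list(seen)

    def subset(self, indices: Iterable[int]) -> "SpectraSet":
        idx = np.asarray(list(indices), dtype=int)
        return SpectraSet(
            grid=self.grid,
            absorbance=self.absorbance[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=None if self.labels is None else [self.labels[i] for i in idx],
        )

    def select_ids(self, ids: Sequence[str]) -> "SpectraSet":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return self.subset([pos[s] for s in ids])

    def with_absorbance(self, new: np.ndarray) -> "SpectraSet":
        return replace(self, absorbance=np.asarray(new, dtype=float))


def read_spectra(path: str | Path, label_column: str = "label") -> SpectraSet:
    """Read a delimited-text spectra file.

    Format: header ``sample_id[,label],<wavenumber...>``, one row per sample,
    ``#`` comment lines, "." decimal separator.  Wavenumber columns may be
    listed descending; they are normalized to ascending order.
    """
    df = pd.read_csv(path, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError("expected sample_id column plus at least 2 wavenumbers")
    cols = list(df.columns)
    has_label = len(cols) > 1 and cols[1] == label_column
    first_spec = 2 if has_label else 1
    try:
        wn = np.array([float(c) for c in cols[first_spec:]])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavenumber in header: {exc}") from None
    values = df.iloc[:, first_spec:].to_numpy(dtype=float)
    if wn.size >= 2 and wn[0] > wn[-1]:
        wn = wn[::-1]
        values = values[:, ::-1]
    grid = WavenumberGrid.from_values(wn)
    labels = df.iloc[:, 1].astype(str).tolist() if has_label else None
    return SpectraSet(
        grid=grid,
        absorbance=values,
        sample_ids=df.iloc[:, 0].astype(str).tolist(),
        labels=labels,
    )


def write_spectra(s: SpectraSet, path: str | Path, label_column: str = "label") -> Path:
    """Write a SpectraSet in the CSV dialect understood by :func:`read_spectra`.

    Values are serialized with 12 significant digits so a round trip is
    lossless to well below measurement precision.
    """
    path = Path(path)
    data: dict[str, object] = {"sample_id": s.sample_ids}
    if s.labels is not None:
        data[label_column] = s.labels
    for j, w in enumerate(s.grid.values):
        data[format(w, ".10g")] = s.absorbance[:, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")
    return path


def mean_spectrum(s: SpectraSet, by_label: bool = False) -> SpectraSet:
    """Column-wise mean spectrum, overall or one row per class."""
    if s.n_samples == 0:
        raise ValueError("empty SpectraSet")
    if not by_label:
        return SpectraSet(
            grid=s.grid,
            absorbance=s.absorbance.mean(axis=0, keepdims=True),
            sample_ids=["mean"],
        )
    if s.labels is None:
        raise ValueError("by_label requires labels")
    classes = s.class_order()
    lab = np.asarray(s.labels)
    rows = [s.absorbance[lab == c].mean(axis=0) for c in classes]
    return SpectraSet(
        grid=s.grid,
        absorbance=np.vstack(rows),
        sample_ids=[f"mean:{c}" for c in classes],
        labels=list(classes),
    )
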