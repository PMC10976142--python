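"""Spectral pretreatments: Savitzky–Golay smoothing/derivatives, SNV, MSC.

Each pretreatment exists both as a scikit-learn transformer operating on
plain 2-D arrays (so it composes with sklearn pipelines) and as a
module-level function operating on :class:`~ephah.spectra.SpectraSet`.

Pipelines are named with the conventional chemometric shorthand, e.g.
``"SNV+SG-17+2D"`` = standard normal variate followed by a 17-point
Savitzky–Golay second derivative; :func:`parse_pipeline_name` parses that
grammar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .spectra import SpectraSet

__all__ = [
    "SavitzkyGolay",
    "SNV",
    "MSC",
    "PreprocessStep",
    "Pipeline",
    "STANDARD_PIPELINES",
    "sg_filter",
    "snv",
    "msc",
    "parse_pipeline_name",
    "apply_pipeline",
]


class SavitzkyGolay(BaseEstimator, TransformerMixin):
    """Per-row Savitzky–Golay filter, optionally a derivative.

    Parameters
    ----------
    window : int
        Odd window length in points, > ``polyorder``.
    polyorder : int
        Local polynomial order.
    deriv : int
        Derivative order (0 = smoothing).  Derivatives are scaled by the
        grid step so they are in physical units (per cm⁻¹, per cm⁻²);
        pass ``delta`` accordingly.
    delta : float
        Abscissa spacing used to scale derivatives.

    Edges use polynomial interpolation (``mode="interp"``) so the number of
    points is preserved.
    """

    def __init__(self, window: int = 17, polyorder: int = 2, deriv: int = 0,
                 delta: float = 1.0):
        self.window = window
        self.polyorder = polyorder
        self.deriv = deriv
        self.delta = delta

    def _validate(self, n_points: int) -> None:
        if self.window % 2 == 0:
            raise ValueError(f"window must be odd, got {self.window}")
        if self.window <= self.polyorder:
            raise ValueError("window must exceed polyorder")
        if self.deriv > self.polyorder:
            raise ValueError("deriv must not exceed polyorder")
        if self.window > n_points:
            raise ValueError(f"window {self.window} exceeds {n_points} points")

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self._validate(X.shape[-1])
        self.n_features_in_ = X.shape[-1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        self._validate(X.shape[-1])
        return savgol_filter(
            X, window_length=self.window, polyorder=self.polyorder,
            deriv=self.deriv, delta=self.delta, axis=-1, mode="interp",
        )


class SNV(BaseEstimator, TransformerMixin):
    """Standard normal variate: each row centered and scaled to unit sd.

    The sample standard deviation (n−1 denominator) is used.  A constant
    row has no scale and raises, identifying the offending sample.
    """

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[-1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        mu = X.mean(axis=-1, keepdims=True)
        sd = X.std(axis=-1, ddof=1, keepdims=True)
        bad = np.flatnonzero(sd.ravel() == 0)
        if bad.size:
            raise ValueError(f"constant spectrum at row(s) {bad.tolist()}: SNV undefined")
        return (X - mu) / sd


class MSC(BaseEstimator, TransformerMixin):
    """Multiplicative scatter correction against a reference spectrum.

    Each row x is regressed on the reference r (x ≈ a·r + b by least
    squares) and replaced by (x − b)/a.  The reference defaults to the mean
    spectrum of the data passed to :meth:`fit`, and is then reused for new
    data — no information leaks from prediction-time spectra.
    """

    def __init__(self, reference: np.ndarray | None = None):
        self.reference = reference

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.reference is not None:
            ref = np.asarray(self.reference, dtype=float)
        else:
            if X.shape[0] < 2:
                raise ValueError("MSC needs ≥2 spectra to learn a reference")
            ref = X.mean(axis=0)
        if np.std(ref) == 0:
            raise ValueError("zero-variance MSC reference")
        self.reference_ = ref
        self.n_features_in_ = X.shape[-1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        r = self.reference_
        rc = r - r.mean()
        denom = float(rc @ rc)
        a = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
        b = X.mean(axis=1) - a * r.mean()
        return (X - b[:, None]) / a[:, None]


# ---------------------------------------------------------------------------
# pipeline grammar

@dataclass(frozen=True)
class PreprocessStep:
    """One pretreatment step: sg-smooth, sg-derivative, snv, or msc."""

    kind: str
    window: int = 0
    polyorder: int = 0
    deriv_order: int = 0

    def token(self) -> str:
        if self.kind == "snv":
            return "SNV"
        if self.kind == "msc":
            return "MSC"
        if self.kind == "sg-smooth":
            return f"SG-{self.window}"
        # derivative: minimal window prints bare, else the compact dD-w form
        # ("SG-w+dD" parses to the same fused step and normalizes to this)
        bare = _minimal_window(self.deriv_order)
        d = f"{self.deriv_order}D"
        return d if self.window == bare else f"{d}-{self.window}"


@dataclass(frozen=True)
class Pipeline:
    """Named ordered sequence of pretreatment steps."""

    steps: tuple[PreprocessStep, ...]
    name: str = ""

    def canonical_name(self) -> str:
        return "+".join(st.token() for st in self.steps)


def _minimal_window(deriv_order: int) -> int:
    """Smallest odd window exceeding the default polyorder."""
    poly = max(2, deriv_order)
    w = poly + 1
    return w if w % 2 == 1 else w + 1


def parse_pipeline_name(name: str) -> Pipeline:
    """Parse chemometric shorthand like ``"SNV+SG-17+2D"``.

    Grammar: ``TOKEN(+TOKEN)*`` with TOKEN ∈ {SG, SG-w, 1D, 2D, 1D-w, 2D-w,
    SNV, MSC}.  ``SG-w`` immediately followed by ``1D``/``2D`` fuses into a
    single derivative step with window w; a bare ``1D``/``2D`` (or window-w
    derivative token ``1D-w``) stands alone.  Windows must be odd.
    """
    tokens = [t.strip() for t in name.split("+") if t.strip()]
    if not tokens:
        raise ValueError("empty pipeline name")
    steps: list[PreprocessStep] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i].upper()
        if tok == "SNV":
            steps.append(PreprocessStep("snv"))
        elif tok == "MSC":
            steps.append(PreprocessStep("msc"))
        elif tok == "SG" or tok.startswith("SG-"):
            window = 17 if tok == "SG" else _parse_window(tok[3:], tok)
            # fuse with a following bare derivative token
            if i + 1 < len(tokens) and tokens[i + 1].upper() in ("1D", "2D"):
                deriv = int(tokens[i + 1][0])
                steps.append(PreprocessStep(
                    "sg-derivative", window=window,
                    polyorder=max(2, deriv), deriv_order=deriv))
                i += 1
            else:
                steps.append(PreprocessStep("sg-smooth", window=window, polyorder=2))
        elif tok in ("1D", "2D") or (len(tok) > 2 and tok[1:3] == "D-"):
            deriv = int(tok[0])
            if deriv not in (1, 2):
                raise ValueError(f"unknown token {tokens[i]!r}")
            window = (_minimal_window(deriv) if tok in ("1D", "2D")
                      else _parse_window(tok[3:], tok))
            steps.append(PreprocessStep(
                "sg-derivative", window=window,
                polyorder=max(2, deriv), deriv_order=deriv))
        else:
            raise ValueError(f"unknown token {tokens[i]!r}")
        i += 1
    return Pipeline(steps=tuple(steps), name=name)


def _parse_window(text: str, tok: str) -> int:
    try:
        w = int(text)
    except ValueError:
        raise ValueError(f"bad window in token {tok!r}") from None
    if w % 2 == 0:
        raise ValueError(f"even window {w} in token {tok!r}")
    return w


#: the standard 15-variant pretreatment comparison catalog (single methods,
#: smoothed derivatives, and SNV/MSC combined with smoothed derivatives);
#: derivative windows must be odd, so even conventional values round to the
#: nearest odd neighbour that keeps all 15 variants distinct
STANDARD_PIPELINES: tuple[str, ...] = (
    "SG-17",
    "1D", "1D-13",
    "2D", "2D-19",
    "SG-5+1D", "SG-21+1D",
    "SG-5+2D", "SG-21+2D",
    "SNV", "SNV+SG-25+1D", "SNV+SG-17+2D",
    "MSC", "MSC+SG-9+1D", "MSC+SG-9+2D",
)


# ---------------------------------------------------------------------------
# SpectraSet-level wrappers

def sg_filter(s: SpectraSet, window: int, polyorder: int = 2,
              deriv_order: int = 0) -> SpectraSet:
    t = SavitzkyGolay(window=window, polyorder=polyorder, deriv=deriv_order,
                      delta=s.grid.step)
    return s.with_absorbance(t.fit_transform(s.absorbance))


def snv(s: SpectraSet) -> SpectraSet:
    sd = s.absorbance.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        ids = [s.sample_ids[i] for i in bad]
        raise ValueError(f"constant spectrum for sample(s) {ids}: SNV undefined")
    return s.with_absorbance(SNV().fit_transform(s.absorbance))


def msc(s: SpectraSet, reference: np.ndarray | None = None) -> SpectraSet:
    t = MSC(reference=reference)
    return s.with_absorbance(t.fit_transform(s.absorbance))


def _step_transformer(st: PreprocessStep, step_cm: float):
    if st.kind == "snv":
        return SNV()
    if st.kind == "msc":
        return MSC()
    if st.kind == "sg-smooth":
        return SavitzkyGolay(window=st.window, polyorder=st.polyorder, deriv=0)
    if st.kind == "sg-derivative":
        return SavitzkyGolay(window=st.window, polyorder=st.polyorder,
                             deriv=st.deriv_order, delta=step_cm)
    raise ValueError(f"unknown step kind {st.kind!r}")


def apply_pipeline(p: Pipeline | str, s: SpectraSet,
                   fit_context: SpectraSet | None = None) -> SpectraSet:
    """Apply a pretreatment pipeline to ``s``.

    When ``fit_context`` is given, data-dependent steps (MSC reference) are
    learned from it instead of from ``s`` — use the training set here when
    transforming validation/test spectra.
    """
    if isinstance(p, str):
        p = parse_pipeline_name(p)
    X = s.absorbance
    ctx = fit_context.absorbance if fit_context is not None else None
    for i, st in enumerate(p.steps):
        t = _step_transformer(st, s.grid.step)
        try:
            if ctx is not None:
                t.fit(ctx)
                ctx = t.transform(ctx)
            else:
                t.fit(X)
            X = t.transform(X)
        except ValueError as exc:
            raise ValueError(f"step {i} ({st.token()}): {exc}") from exc
    return s.with_absorbance(X)
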