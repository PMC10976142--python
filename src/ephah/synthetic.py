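"""Seeded generator of class-structured NIR spectra with injected outliers.

The generator emulates the band structure of polyethylene packaging
microplastics carrying phthalate (PAE) plasticizer: a set of methylene
combination/overtone peaks shared by every class (4250, 4323, 5245, 5338,
5390, 5440, 5700, 5773, 5940, 7010, 7230, 7340, 7378 cm⁻¹) plus an ester
band in the 5160–5500 cm⁻¹ second-overtone region.  Classes share all band
positions and differ only in small relative amplitude perturbations, the
situation that makes large-class-number classification hard.

Per-sample nuisance terms model the usual NIR measurement effects:
multiplicative scatter gain, additive offset, a random low-degree polynomial
baseline, and i.i.d. Gaussian noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .spectra import DEFAULT_GRID, SpectraSet, WavenumberGrid

__all__ = [
    "BandSpec",
    "ClassProfile",
    "SimulationConfig",
    "SHARED_PEAKS",
    "default_profiles",
    "simulate_spectra",
    "inject_outliers",
]

#: shared methylene combination/overtone peak centers, cm⁻¹
SHARED_PEAKS: tuple[float, ...] = (
    4250.0, 4323.0, 5245.0, 5338.0, 5390.0, 5440.0, 5700.0,
    5773.0, 5940.0, 7010.0, 7230.0, 7340.0, 7378.0,
)

#: ester (R-COO-R') second-overtone band center, cm⁻¹ (within 5160–5500)
ESTER_BAND_CENTER = 5300.0


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band."""

    center: float
    width: float      # Gaussian sigma, cm⁻¹
    amplitude: float  # peak absorbance

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be non-negative")


@dataclass(frozen=True)
class ClassProfile:
    """A class's band set plus its relative amplitude perturbations.

    ``band_perturbation`` holds the class's mean relative amplitude offsets;
    individual samples additionally jitter around that mean (see
    :class:`SimulationConfig.intra_jitter`), which is what makes classes
    overlap rather than being separated by a clean noise floor.
    """

    class_name: str
    bands: tuple[BandSpec, ...]
    band_perturbation: tuple[float, ...]  # relative amplitude offsets, one per band

    def __post_init__(self) -> None:
        if len(self.band_perturbation) != len(self.bands):
            raise ValueError("one perturbation per band required")

    def pure_spectrum(self, grid: WavenumberGrid) -> np.ndarray:
        """Noise-free class spectrum: sum of perturbed Gaussian bands."""
        wn = grid.values
        out = np.zeros(grid.n_points)
        for band, pert in zip(self.bands, self.band_perturbation):
            amp = band.amplitude * (1.0 + pert)
            if amp <= 0:
                continue
            out += amp * np.exp(-0.5 * ((wn - band.center) / band.width) ** 2)
        return out


#: class sizes of the reference 750-spectrum packaging data set
REFERENCE_CLASS_SIZES: tuple[int, ...] = (75, 75, 84, 85, 85, 74, 74, 69, 65, 60)


@dataclass
class SimulationConfig:
    """Full description of one synthetic acquisition run.

    The seed fully determines the output; it fans out to independent
    substreams for profiles, scatter, baseline, noise and outliers so stages
    can be regenerated independently.
    """

    grid: WavenumberGrid = DEFAULT_GRID
    n_classes: int = 10
    samples_per_class: tuple[int, ...] = REFERENCE_CLASS_SIZES
    noise_sd: float = 5e-4
    baseline_poly_degree: int = 2
    baseline_scale: float = 0.05
    scatter_gain_sd: float = 0.05
    scatter_offset_sd: float = 0.01
    class_separation: float = 0.015
    intra_jitter: float = 0.01
    outlier_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if isinstance(self.samples_per_class, int):
            self.samples_per_class = (self.samples_per_class,) * self.n_classes
        self.samples_per_class = tuple(self.samples_per_class)
        if len(self.samples_per_class) != self.n_classes:
            raise ValueError("samples_per_class length must equal n_classes")
        for name in ("noise_sd", "baseline_scale", "scatter_gain_sd",
                     "scatter_offset_sd", "class_separation", "intra_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")


def _substream(seed: int, stage: str) -> np.random.Generator:
    # crc32 is stable across processes, unlike the builtin str hash
    tag = zlib.crc32(stage.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def default_profiles(
    n_classes: int, separation: float = 0.015, seed: int = 0
) -> list[ClassProfile]:
    """Build per-class band profiles sharing the methylene + ester band set.

    Every profile carries the 13 shared methylene peaks plus the ester band;
    class differences are zero-mean Gaussian relative amplitude offsets of
    standard deviation ``separation``, independent per band.
    ``separation=0`` makes all classes identical (a pure chance-level
    problem).
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    rng = _substream(seed, "profiles")
    centers = list(SHARED_PEAKS) + [ESTER_BAND_CENTER]
    # widths drawn once (shared across classes) in 15–40 cm⁻¹ so adjacent
    # peaks partially overlap, as in real un-preprocessed NIR spectra
    widths = rng.uniform(15.0, 40.0, size=len(centers))
    amplitudes = rng.uniform(0.2, 1.0, size=len(centers))
    bands = tuple(
        BandSpec(center=c, width=float(w), amplitude=float(a))
        for c, w, a in zip(centers, widths, amplitudes)
    )
    profiles = []
    for i in range(n_classes):
        pert = rng.normal(0.0, 1.0, size=len(bands)) * separation
        profiles.append(
            ClassProfile(
                class_name=f"C{i + 1:02d}",
                bands=bands,
                band_perturbation=tuple(float(p) for p in pert),
            )
        )
    return profiles


def simulate_spectra(
    cfg: SimulationConfig, profiles: Sequence[ClassProfile] | None = None
) -> SpectraSet:
    """Simulate a labeled SpectraSet under ``cfg``.

    Each spectrum is ``(class band sum with per-sample amplitude jitter) ×
    (1 + gain) + offset + baseline(ν) + noise`` with per-sample gain ~
    N(0, scatter_gain_sd), offset ~ N(0, scatter_offset_sd), a random
    polynomial baseline of the configured degree, and i.i.d. N(0, noise_sd)
    noise.  The amplitude jitter (relative sd ``intra_jitter``, independent
    per band) models sample-to-sample composition differences within a
    class; together with ``class_separation`` it sets how much the classes
    overlap.
    """
    if profiles is None:
        profiles = default_profiles(cfg.n_classes, cfg.class_separation, cfg.seed)
    if len(profiles) != cfg.n_classes:
        raise ValueError("profile count must equal n_classes")
    grid = cfg.grid
    rng = _substream(cfg.seed, "spectra")
    # normalized axis in [-1, 1] keeps polynomial baseline terms comparable
    u = np.linspace(-1.0, 1.0, grid.n_points)
    wn = grid.values
    rows, ids, labels = [], [], []
    for profile, n_c in zip(profiles, cfg.samples_per_class):
        # band shape matrix (n_bands × n_points), amplitudes folded in later
        shapes = np.array([
            np.exp(-0.5 * ((wn - b.center) / b.width) ** 2)
            for b in profile.bands
        ])
        amp0 = np.array([b.amplitude for b in profile.bands])
        pert_c = np.asarray(profile.band_perturbation)
        for j in range(n_c):
            pert = pert_c
            if cfg.intra_jitter > 0:
                pert = pert + rng.normal(0.0, cfg.intra_jitter, size=pert.size)
            amps = np.clip(amp0 * (1.0 + pert), 0.0, None)
            pure = amps @ shapes
            gain = 1.0 + rng.normal(0.0, cfg.scatter_gain_sd)
            offset = rng.normal(0.0, cfg.scatter_offset_sd)
            baseline = np.zeros(grid.n_points)
            if cfg.baseline_scale > 0:
                coefs = rng.normal(0.0, cfg.baseline_scale,
                                   size=cfg.baseline_poly_degree + 1)
                baseline = np.polynomial.polynomial.polyval(u, coefs)
            noise = (rng.normal(0.0, cfg.noise_sd, size=grid.n_points)
                     if cfg.noise_sd > 0 else 0.0)
            rows.append(pure * gain + offset + baseline + noise)
            ids.append(f"{profile.class_name}-{j + 1:03d}")
            labels.append(profile.class_name)
    return SpectraSet(grid=grid, absorbance=np.vstack(rows),
                      sample_ids=ids, labels=labels)


OutlierMode = Literal["shifted-baseline", "alien-band", "extreme-leverage"]


def inject_outliers(
    s: SpectraSet,
    fraction: float,
    mode: OutlierMode = "alien-band",
    seed: int = 0,
) -> tuple[SpectraSet, list[str]]:
    """Return a copy of ``s`` with a fraction of spectra turned into outliers.

    Modes target the two PCA outlier diagnostics: ``alien-band`` adds a
    Gaussian band at a wavenumber where no class absorbs (high orthogonal
    distance); ``extreme-leverage`` inflates a spectrum along the dominant
    principal direction of the set (high score distance);
    ``shifted-baseline`` adds a large constant offset.
    """
    if s.n_samples == 0:
        raise ValueError("empty SpectraSet")
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    n_out = int(round(fraction * s.n_samples))
    if fraction > 0 and n_out < 1:
        raise ValueError("fraction too small: selects no sample")
    if n_out == 0:
        return s.with_absorbance(s.absorbance.copy()), []
    rng = _substream(seed, "outliers")
    idx = rng.choice(s.n_samples, size=n_out, replace=False)
    X = s.absorbance.copy()
    wn = s.grid.values
    if mode == "alien-band":
        # a chemically foreign absorption of weak-band strength, centered in
        # the region (~85 % of the axis) where no profile band absorbs
        center = wn[int(0.85 * len(wn))]
        bump = np.exp(-0.5 * ((wn - center) / 25.0) ** 2)
        for i in idx:
            X[i] = X[i] + 0.2 * bump
    elif mode == "extreme-leverage":
        center = X.mean(axis=0)
        Xc = X - center
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        sd1 = float(np.std(Xc @ vt[0], ddof=1))
        for i in idx:
            X[i] = X[i] + 8.0 * sd1 * vt[0]
    elif mode == "shifted-baseline":
        for i in idx:
            X[i] = X[i] + 0.5
    else:
        raise ValueError(f"unknown outlier mode {mode!r}")
    out = s.with_absorbance(X)
    return out, [s.sample_ids[i] for i in sorted(idx)]
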