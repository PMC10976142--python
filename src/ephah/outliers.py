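"""PCA-based outlier screening with score and orthogonal distances.

A PCA model (robust median centering by default) is fitted per class; each
sample gets a score distance SD (Mahalanobis distance in the retained score
space) and an orthogonal distance OD (residual norm off the PC subspace).
Hotelling-T²-style F limits give the cutoffs:

    SD² limit:  p(n−1)/(n−p) · F(α; p, n−p)
    OD  limit:  p(n−1)(n+1)/(n(n−p)) · F(α; p, n−p)

so the OD/SD limit ratio is exactly (n+1)/n.  SD² is compared with the SD²
limit directly.  The raw OD is in absorbance-residual units, so for
comparison with the F-scale limit it is standardized to
``p · OD² / median(OD²)`` over the fitted class — a typical sample then
scores near p, the same scale on which SD² lives.

Four categories follow from the two flags: regular (low/low), good-leverage
(high SD only), orthogonal-outlier (high OD only), bad-leverage (high/high).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .spectra import SpectraSet

__all__ = [
    "PCAModel",
    "OutlierReport",
    "PCAOutlierScreen",
    "fit_pca",
    "score_distance",
    "orthogonal_distance",
    "sd_cutoff",
    "od_cutoff",
    "screen_outliers",
]

CATEGORIES = ("regular", "good-leverage", "orthogonal-outlier", "bad-leverage")


@dataclass
class PCAModel:
    """Centered PCA: loadings (n_points × p), score variances, sample count."""

    center: np.ndarray
    loadings: np.ndarray      # columns orthonormal
    eigenvalues: np.ndarray   # score variances, descending
    p: int
    n: int
    explained_variance_ratio: np.ndarray | None = None

    def scores(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.center) @ self.loadings


def fit_pca(
    s: SpectraSet | np.ndarray,
    p: int | None = None,
    cumvar_target: float = 0.999,
    center: str = "median",
) -> PCAModel:
    """Fit a PCA model, choosing p by cumulative explained variance.

    ``center="median"`` (default) centers on the column-wise median for
    resistance to masking by outliers; ``"mean"`` gives classical PCA.
    Score variances use the n−1 denominator.
    """
    X = s.absorbance if isinstance(s, SpectraSet) else np.asarray(s, float)
    n = X.shape[0]
    if not 0 < cumvar_target <= 1:
        raise ValueError("cumvar_target must be in (0, 1]")
    if center == "median":
        c = np.median(X, axis=0)
    elif center == "mean":
        c = X.mean(axis=0)
    else:
        raise ValueError(f"unknown centering {center!r}")
    Xc = X - c
    # SVD gives loadings and score variances in one pass
    _, sv, vt = np.linalg.svd(Xc, full_matrices=False)
    var = sv**2 / (n - 1)
    total = var.sum()
    if total == 0:
        raise ValueError("degenerate data: all spectra identical")
    ratio = var / total
    if p is None:
        cum = np.cumsum(ratio)
        p = int(np.searchsorted(cum, cumvar_target - 1e-12) + 1)
        p = min(p, len(var))
    if p < 1 or p > len(var):
        raise ValueError(f"p={p} out of range for rank-{len(var)} data")
    if n < p + 1:
        raise ValueError("need n ≥ p+1 samples")
    return PCAModel(
        center=c,
        loadings=vt[:p].T.copy(),
        eigenvalues=var[:p].copy(),
        p=p,
        n=n,
        explained_variance_ratio=ratio,
    )


def score_distance(m: PCAModel, s: SpectraSet | np.ndarray) -> np.ndarray:
    """Mahalanobis distance in score space: sqrt(Σ_k t_k²/λ_k)."""
    X = s.absorbance if isinstance(s, SpectraSet) else np.asarray(s, float)
    if np.any(m.eigenvalues <= 0):
        raise ValueError("zero eigenvalue among retained components")
    t = m.scores(X)
    return np.sqrt(((t**2) / m.eigenvalues).sum(axis=1))


def orthogonal_distance(m: PCAModel, s: SpectraSet | np.ndarray) -> np.ndarray:
    """Euclidean norm of the residual off the PC subspace."""
    X = s.absorbance if isinstance(s, SpectraSet) else np.asarray(s, float)
    Xc = X - m.center
    t = Xc @ m.loadings
    resid = Xc - t @ m.loadings.T
    return np.linalg.norm(resid, axis=1)


def sd_cutoff(p: int, n: int, alpha: float = 0.95) -> float:
    """Hotelling T² limit p(n−1)/(n−p)·F(α; p, n−p) for SD² (printed scale)."""
    if n <= p:
        raise ValueError("need n > p")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return p * (n - 1) / (n - p) * stats.f.ppf(alpha, p, n - p)


def od_cutoff(p: int, n: int, alpha: float = 0.95) -> float:
    """D-statistic limit p(n−1)(n+1)/(n(n−p))·F(α; p, n−p), = (n+1)/n × SD limit."""
    return sd_cutoff(p, n, alpha) * (n + 1) / n


@dataclass
class OutlierReport:
    """Per-sample screening result over one SpectraSet."""

    sample_ids: list[str]
    labels: list[str] | None
    sd: np.ndarray                # raw score distance
    od: np.ndarray                # raw orthogonal distance (absorbance units)
    sd_stat: np.ndarray           # SD² on the T² scale
    od_stat: np.ndarray           # standardized p·OD²/median(OD²)
    sd_cutoffs: np.ndarray        # per-sample cutoff (from its class model)
    od_cutoffs: np.ndarray
    category: list[str]
    removed: np.ndarray           # bool mask
    pcs_per_class: dict[str, int]

    @property
    def removed_ids(self) -> list[str]:
        return [s for s, r in zip(self.sample_ids, self.removed) if r]

    def kept(self, s: SpectraSet) -> SpectraSet:
        keep = [i for i, r in enumerate(self.removed) if not r]
        return s.subset(keep)


def _categorize(high_sd: bool, high_od: bool) -> str:
    if high_sd and high_od:
        return "bad-leverage"
    if high_od:
        return "orthogonal-outlier"
    if high_sd:
        return "good-leverage"
    return "regular"


#: removal policies: "either" removes anything beyond either cutoff;
#: "high-od" removes only orthogonal-outlier and bad-leverage samples.
POLICIES = ("either", "high-od")


def screen_outliers(
    s: SpectraSet,
    policy: str = "either",
    alpha: float = 0.95,
    per_class: bool = True,
    p: int | None = None,
    cumvar_target: float = 0.999,
    center: str = "median",
    prediction_set: bool = True,
) -> OutlierReport:
    """Screen a SpectraSet for abnormal samples.

    Fits a PCA model per class (default) or globally, computes SD/OD and
    their F-based cutoffs, assigns the four-way category, and flags removals
    under the chosen policy.

    With ``prediction_set=True`` (default) each sample is cycled into a
    prediction set: its SD/OD come from a PCA model fitted on the other
    n−1 class members, so a gross outlier cannot pull the subspace toward
    itself and mask its own residual.  The component count p is chosen once
    per class on the full fit and reused for the leave-one-out refits.
    ``prediction_set=False`` scores every sample against the single full
    fit (faster, but a lone extreme sample can absorb into the model).
    """
    if policy not in POLICIES:
        raise ValueError(f"policy must be one of {POLICIES}")
    if per_class and s.labels is None:
        raise ValueError("per_class screening requires labels")
    n = s.n_samples
    sd = np.empty(n)
    od = np.empty(n)
    sd_stat = np.empty(n)
    od_stat = np.empty(n)
    sd_cut = np.empty(n)
    od_cut = np.empty(n)
    category: list[str] = [""] * n
    pcs: dict[str, int] = {}

    groups: list[tuple[str, np.ndarray]]
    if per_class:
        lab = np.asarray(s.labels)
        groups = [(c, np.flatnonzero(lab == c)) for c in s.class_order()]
    else:
        groups = [("(all)", np.arange(n))]

    for cname, idx in groups:
        sub = s.absorbance[idx]
        model = fit_pca(sub, p=p, cumvar_target=cumvar_target, center=center)
        if len(idx) <= model.p + 1:
            raise ValueError(f"class {cname!r} too small for p={model.p}")
        pcs[cname] = model.p
        if prediction_set:
            sd_g = np.empty(len(idx))
            od_g = np.empty(len(idx))
            for j in range(len(idx)):
                keep = np.delete(np.arange(len(idx)), j)
                loo = fit_pca(sub[keep], p=model.p, center=center)
                row = sub[j:j + 1]
                sd_g[j] = score_distance(loo, row)[0]
                od_g[j] = orthogonal_distance(loo, row)[0]
        else:
            sd_g = score_distance(model, sub)
            od_g = orthogonal_distance(model, sub)
        med_od2 = float(np.median(od_g**2))
        odstat_g = (model.p * od_g**2 / med_od2) if med_od2 > 0 else np.zeros_like(od_g)
        sc = sd_cutoff(model.p, model.n, alpha)
        oc = od_cutoff(model.p, model.n, alpha)
        for j, i in enumerate(idx):
            sd[i], od[i] = sd_g[j], od_g[j]
            sd_stat[i], od_stat[i] = sd_g[j] ** 2, odstat_g[j]
            sd_cut[i], od_cut[i] = sc, oc
            category[i] = _categorize(sd_stat[i] > sc, od_stat[i] > oc)

    cat = np.asarray(category)
    if policy == "either":
        removed = cat != "regular"
    else:  # high-od
        removed = np.isin(cat, ("orthogonal-outlier", "bad-leverage"))
    return OutlierReport(
        sample_ids=list(s.sample_ids),
        labels=None if s.labels is None else list(s.labels),
        sd=sd, od=od, sd_stat=sd_stat, od_stat=od_stat,
        sd_cutoffs=sd_cut, od_cutoffs=od_cut,
        category=category, removed=removed, pcs_per_class=pcs,
    )


class PCAOutlierScreen(BaseEstimator):
    """Scikit-learn-style wrapper around PCA SD/OD screening.

    ``fit(X)`` learns the PCA model; ``predict(X)`` returns +1 for regular
    samples and −1 for samples beyond either cutoff (sklearn outlier
    convention).  Fitted attributes: ``sd_``, ``od_``, ``sd_cutoff_``,
    ``od_cutoff_``, ``categories_`` for the training data.
    """

    def __init__(self, p: int | None = None, cumvar_target: float = 0.999,
                 alpha: float = 0.95, center: str = "median"):
        self.p = p
        self.cumvar_target = cumvar_target
        self.alpha = alpha
        self.center = center

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.model_ = fit_pca(X, p=self.p, cumvar_target=self.cumvar_target,
                              center=self.center)
        self.sd_ = score_distance(self.model_, X)
        self.od_ = orthogonal_distance(self.model_, X)
        self._median_od2_ = float(np.median(self.od_**2))
        self.sd_cutoff_ = sd_cutoff(self.model_.p, self.model_.n, self.alpha)
        self.od_cutoff_ = od_cutoff(self.model_.p, self.model_.n, self.alpha)
        self.categories_ = self._categorize(self.sd_, self.od_)
        return self

    def _categorize(self, sd: np.ndarray, od: np.ndarray) -> list[str]:
        od_stat = (self.model_.p * od**2 / self._median_od2_
                   if self._median_od2_ > 0 else np.zeros_like(od))
        return [
            _categorize(s2 > self.sd_cutoff_, o2 > self.od_cutoff_)
            for s2, o2 in zip(sd**2, od_stat)
        ]

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        cats = self._categorize(score_distance(self.model_, X),
                                orthogonal_distance(self.model_, X))
        return np.where(np.asarray(cats) == "regular", 1, -1)
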