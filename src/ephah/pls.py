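"""NIPALS partial least squares, binary PLS-DA, RMSECV and Monte Carlo CV.

The PLS1 core is the classical NIPALS recursion with X-deflation.  For a
single response the weight vector of each component is the (normalized)
covariance direction X'y, so no inner iteration is needed and the fit is
exactly deterministic.  Regression coefficients are accumulated per
component, giving the whole family of nested models (1..A latent
variables) from one fit — cross-validation exploits this.

Model complexity (the latent-variable count) is selected by Monte Carlo
cross-validation: over many random stratified holdouts, the
misclassification error rate is

    ERMCCV = Σ_i M_i / N

with M_i the misjudged count of split i and N the total number of tested
objects; the LV count minimizing ERMCCV wins, smaller counts breaking ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.model_selection import KFold, StratifiedShuffleSplit

__all__ = [
    "PLSRegressionNIPALS",
    "PLSDABinary",
    "MCCVResult",
    "AccuracyResult",
    "fit_pls",
    "predict_response",
    "rmsecv",
    "rmsecv_curve",
    "mccv_select_lvs",
    "classification_accuracy",
]


class PLSRegressionNIPALS(BaseEstimator, RegressorMixin):
    """PLS1 regression via NIPALS with mean centering (no variance scaling).

    Parameters
    ----------
    n_components : int
        Number of latent variables A.

    Fitted attributes
    -----------------
    x_mean_, y_mean_ : centering vectors
    x_weights_ : (n_features, A) weight vectors w_a
    x_loadings_ : (n_features, A) loadings p_a
    y_loadings_ : (A,) response loadings q_a
    coef_ : (n_features,) regression vector at A components
    coef_path_ : (A, n_features) coefficients of every nested model
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, m = X.shape
        if y.size != n:
            raise ValueError("X and y sizes disagree")
        if np.allclose(y, y[0]):
            raise ValueError("zero-variance response")
        A = self.n_components
        if A < 1 or A > min(n - 1, m):
            raise ValueError(f"n_components={A} out of range for {n}×{m} data")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_

        W = np.zeros((m, A))
        P = np.zeros((m, A))
        q = np.zeros(A)
        T = np.zeros((n, A))
        R = np.zeros((m, A))           # R = W (P'W)^{-1}, built column-wise
        coef_path = np.zeros((A, m))
        coef = np.zeros(m)
        actual = 0
        for a in range(A):
            w = Xc.T @ yc
            nw = np.linalg.norm(w)
            if nw <= np.finfo(float).eps * 100:
                break  # X fully deflated: no covariance left
            w /= nw
            t = Xc @ w
            tt = float(t @ t)
            if tt <= np.finfo(float).eps * 100:
                break
            p = Xc.T @ t / tt
            qa = float(yc @ t / tt)
            Xc = Xc - np.outer(t, p)
            W[:, a], P[:, a], q[a], T[:, a] = w, p, qa, t
            r = w - R[:, :a] @ (P[:, :a].T @ w)
            R[:, a] = r
            coef = coef + qa * r
            coef_path[a] = coef
            actual += 1
        if actual == 0:
            raise ValueError("no usable PLS component (X constant?)")
        if actual < A:
            coef_path[actual:] = coef_path[actual - 1]
        self.n_components_ = actual
        self.x_weights_ = W[:, :A]
        self.x_loadings_ = P[:, :A]
        self.y_loadings_ = q[:A]
        self.x_scores_ = T[:, :A]
        self.coef_ = coef_path[A - 1]
        self.coef_path_ = coef_path
        return self

    def predict(self, X, n_components: int | None = None):
        X = np.asarray(X, dtype=float)
        coef = (self.coef_ if n_components is None
                else self.coef_path_[n_components - 1])
        return (X - self.x_mean_) @ coef + self.y_mean_

    def predict_all(self, X) -> np.ndarray:
        """Predictions of every nested model, shape (A, n_samples)."""
        X = np.asarray(X, dtype=float)
        return self.coef_path_ @ (X - self.x_mean_).T + self.y_mean_


class PLSDABinary(BaseEstimator, ClassifierMixin):
    """Binary PLS-DA: PLS1 on a ±1 coded response with a decision threshold.

    ``y`` may be given directly as ±1 or as two class labels (the first
    label encountered codes +1).  Predicted response ≥ ``threshold_c``
    assigns the positive class.
    """

    def __init__(self, n_components: int = 2, threshold_c: float = 0.0):
        self.n_components = n_components
        self.threshold_c = threshold_c

    def fit(self, X, y):
        y = np.asarray(y)
        if y.dtype.kind in ("U", "S", "O"):
            classes = list(dict.fromkeys(y.tolist()))
            if len(classes) != 2:
                raise ValueError("PLSDABinary needs exactly 2 classes")
            self.classes_ = np.asarray(classes)
            coded = np.where(y == classes[0], 1.0, -1.0)
        else:
            coded = y.astype(float)
            uniq = np.unique(coded)
            if not np.all(np.isin(uniq, (-1.0, 1.0))) or uniq.size != 2:
                raise ValueError("numeric y must contain both +1 and -1")
            self.classes_ = np.asarray([1.0, -1.0])
        self.pls_ = PLSRegressionNIPALS(self.n_components).fit(X, coded)
        return self

    def decision_function(self, X):
        return self.pls_.predict(X) - self.threshold_c

    def predict(self, X):
        pos = self.decision_function(X) >= 0
        return np.where(pos, self.classes_[0], self.classes_[1])


# ---------------------------------------------------------------------------
# cross-validation

def _cap_lv(n_lv: int, n_train: int, n_feat: int) -> int:
    return max(1, min(n_lv, n_train - 1, n_feat))


def rmsecv_curve(X, y, max_lv: int, n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Cross-validated RMSE at every LV count 1..max_lv (one fit per fold)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if n_folds < 2:
        raise ValueError("need n_folds ≥ 2")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    sq = np.zeros(max_lv)
    n_tot = 0
    for tr, te in kf.split(X):
        a = _cap_lv(max_lv, len(tr), X.shape[1])
        model = PLSRegressionNIPALS(a).fit(X[tr], y[tr])
        preds = model.predict_all(X[te])              # (a, n_te)
        resid = preds - y[te]
        sq_fold = (resid**2).sum(axis=1)
        sq[:a] += sq_fold
        if a < max_lv:                                 # pad with the deepest model
            sq[a:] += sq_fold[-1]
        n_tot += len(te)
    return np.sqrt(sq / n_tot)


def rmsecv(X, y, n_lv: int, n_folds: int = 5, seed: int = 0) -> float:
    """Cross-validated RMSE at a single LV count."""
    return float(rmsecv_curve(X, y, n_lv, n_folds, seed)[n_lv - 1])


@dataclass
class MCCVResult:
    """Monte Carlo CV latent-variable selection summary."""

    error_rates: np.ndarray        # ERMCCV per candidate LV count (1-based)
    chosen_n_lv: int
    n_splits: int
    misjudged_per_split: np.ndarray  # M_i at the chosen LV count
    n_tested: int                  # N of the ERMCCV formula

    @property
    def chosen_error_rate(self) -> float:
        return float(self.error_rates[self.chosen_n_lv - 1])


def mccv_select_lvs(
    X,
    y,
    max_lv: int = 10,
    n_splits: int = 100,
    holdout_fraction: float = 0.2,
    seed: int = 0,
    threshold_c: float = 0.0,
) -> MCCVResult:
    """Choose the LV count minimizing the MCCV misclassification rate.

    ``y`` is a ±1 coded response.  Each of ``n_splits`` random stratified
    holdouts contributes its misjudged count M_i; ERMCCV = Σ M_i / N with N
    the total tested.  Ties go to the smallest LV count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if max_lv < 1:
        raise ValueError("max_lv must be ≥ 1")
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must be in (0, 1)")
    sss = StratifiedShuffleSplit(n_splits=n_splits, test_size=holdout_fraction,
                                 random_state=seed % (2**31))
    mis = np.zeros((n_splits, max_lv), dtype=int)
    n_tested = 0
    for si, (tr, te) in enumerate(sss.split(X, y)):
        a = _cap_lv(max_lv, len(tr), X.shape[1])
        model = PLSRegressionNIPALS(a).fit(X[tr], y[tr])
        preds = model.predict_all(X[te])             # (a, n_te)
        signs = np.where(preds >= threshold_c, 1.0, -1.0)
        m = (signs != y[te]).sum(axis=1)
        mis[si, :a] = m
        if a < max_lv:
            mis[si, a:] = m[-1]
        n_tested += len(te)
    error_rates = mis.sum(axis=0) / n_tested
    chosen = int(np.argmin(error_rates)) + 1
    return MCCVResult(
        error_rates=error_rates,
        chosen_n_lv=chosen,
        n_splits=n_splits,
        misjudged_per_split=mis[:, chosen - 1],
        n_tested=n_tested,
    )


@dataclass
class AccuracyResult:
    """Classification accuracy CA = n_correct / n_total."""

    n_correct: int
    n_total: int

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total


def classification_accuracy(n_correct: int, n_total: int) -> AccuracyResult:
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_correct <= n_total:
        raise ValueError("need 0 ≤ n_correct ≤ n_total")
    return AccuracyResult(n_correct=n_correct, n_total=n_total)


# thin functional wrappers ---------------------------------------------------

def fit_pls(X, y, n_lv: int) -> PLSRegressionNIPALS:
    """Fit a NIPALS PLS1 model with ``n_lv`` latent variables."""
    return PLSRegressionNIPALS(n_components=n_lv).fit(X, y)


def predict_response(model: PLSRegressionNIPALS, X, n_components: int | None = None):
    """Predicted response ŷ = (X − x̄)·coef + ȳ."""
    return model.predict(X, n_components=n_components)
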