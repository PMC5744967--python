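"""Univariate partial least squares regression by NIPALS, with RMSEP-based
component selection and Selectivity-Ratio wavelength importance.

For a single response the NIPALS weight of each component is proportional
to X'y of the deflated predictors, so the algorithm is direct (no inner
iteration) and fully deterministic.  The regression vector b satisfies
b = W (P'W)^-1 q, reproducing the component-wise predictions exactly; with
as many components as the predictor rank it reproduces minimum-norm least
squares.

Selectivity Ratio (SR): predictors are projected onto the normalised
regression vector (target projection); SR at wavelength j is the ratio of
the variance of column j explained by that single component to its residual
variance.  Large SR marks wavelengths whose variation is aligned with the
predictive direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold

__all__ = [
    "PLSRegressionNIPALS",
    "WavelengthImportance",
    "fit_plsr",
    "select_ncomp",
    "selectivity_ratio",
]


class PLSRegressionNIPALS(RegressorMixin, BaseEstimator):
    """NIPALS partial least squares regression for a single response.

    Fitted attributes
    -----------------
    x_weights_ : (p, K) component weights W (unit norm per column)
    x_loadings_ : (p, K) loadings P
    y_loadings_ : (K,) loadings q
    x_scores_ : (n, K) scores T (mutually orthogonal)
    coef_ : (p,) regression vector for the selected component count
    coef_path_ : (p, K) regression vectors for 1..K components (nested)
    intercept_ : float
    """

    def __init__(self, n_components: int = 2, center: bool = True):
        self.n_components = n_components
        self.center = center

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-d with one row per element of y")
        n, p = X.shape
        K = int(self.n_components)
        if K < 1 or K > min(n - 1, p):
            raise ValueError(
                f"n_components={K} outside [1, min(n_samples-1, n_features)]")
        if np.ptp(y) == 0:
            raise ValueError("y has zero variance")

        self.x_mean_ = X.mean(axis=0) if self.center else np.zeros(p)
        self.y_mean_ = float(y.mean()) if self.center else 0.0
        Xd = X - self.x_mean_
        yd = y - self.y_mean_

        W = np.zeros((p, K))
        P = np.zeros((p, K))
        q = np.zeros(K)
        T = np.zeros((n, K))
        for k in range(K):
            w = Xd.T @ yd
            norm = np.linalg.norm(w)
            if norm <= 1e-14 * max(1.0, np.abs(yd).max()):
                # residual X carries no covariance with y; truncate
                K = k
                break
            w /= norm
            t = Xd @ w
            tt = t @ t
            if tt <= 0:
                K = k
                break
            pk = Xd.T @ t / tt
            qk = yd @ t / tt
            Xd = Xd - np.outer(t, pk)
            yd = yd - qk * t
            W[:, k], P[:, k], q[k], T[:, k] = w, pk, qk, t
        if K == 0:
            raise ValueError("X carries no covariance with y; cannot fit")
        W, P, q, T = W[:, :K], P[:, :K], q[:, ][:K], T[:, :K]

        # b_k = W_k (P_k' W_k)^-1 q_k ; (P'W) is upper triangular with unit
        # diagonal in NIPALS, so the nested path solves by back-substitution.
        PtW = P.T @ W
        coef_path = np.zeros((p, K))
        for k in range(1, K + 1):
            bk = np.linalg.solve(PtW[:k, :k], q[:k])
            coef_path[:, k - 1] = W[:, :k] @ bk
        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = q
        self.x_scores_ = T
        self.coef_path_ = coef_path
        self.n_components_ = K
        self.coef_ = coef_path[:, K - 1]
        self.intercept_ = self.y_mean_ - self.x_mean_ @ self.coef_
        return self

    def predict(self, X, n_components: int | None = None):
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        one_d = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != self.coef_.shape[0]:
            raise ValueError("X has a different number of wavelengths than "
                             "the fitted model")
        if n_components is None:
            b = self.coef_
        else:
            if not 1 <= n_components <= self.n_components_:
                raise ValueError("n_components outside fitted range")
            b = self.coef_path_[:, n_components - 1]
        out = (X - self.x_mean_) @ b + self.y_mean_
        return out[0] if one_d else out

    def predict_path(self, X):
        """Predictions for every component count 1..K at once: (n, K)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean_) @ self.coef_path_ + self.y_mean_


def fit_plsr(X, y, n_components: int) -> PLSRegressionNIPALS:
    """Thin functional wrapper over :class:`PLSRegressionNIPALS`."""
    return PLSRegressionNIPALS(n_components=n_components).fit(X, y)


def select_ncomp(X, y, max_components: int = 10, cv_folds: int = 10,
                 seed: int = 0, rescale_within_folds: bool = False,
                 return_curve: bool = False):
    """Choose the component count minimising cross-validated RMSEP.

    RMSEP is pooled over a seeded shuffled K-fold split for each candidate
    count 1..max_components (capped by fold training size); the global
    minimiser is returned, ties broken toward fewer components.

    With ``rescale_within_folds=True`` the per-wavelength autoscaling and
    centring statistics are re-estimated inside each training fold (pass X
    after the row-wise SNV/derivative stages, before column scaling), which
    keeps component selection free of any column-statistic leakage.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    if n < cv_folds:
        raise ValueError(f"fewer samples ({n}) than folds ({cv_folds})")
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    kmax = min(max_components, X.shape[1])
    press = np.zeros(kmax)
    counts = np.zeros(kmax, dtype=int)
    for tr, te in kf.split(X):
        Xtr, Xte = X[tr], X[te]
        if rescale_within_folds:
            sd = Xtr.std(axis=0, ddof=1)
            sd = np.where(sd > 1e-15, sd, 1.0)
            Xtr, Xte = Xtr / sd, Xte / sd
        kfold = min(kmax, len(tr) - 1)
        model = PLSRegressionNIPALS(n_components=kfold).fit(Xtr, y[tr])
        kfit = model.n_components_
        pred = model.predict_path(Xte)  # (n_te, kfit)
        err2 = (pred - y[te, None]) ** 2
        press[:kfit] += err2.sum(axis=0)
        if kfit < kmax:  # saturated fits stand in for larger counts
            press[kfit:] += err2[:, -1].sum()
        counts[:] += len(te)
    rmsep = np.sqrt(press / counts)
    best = int(np.argmin(rmsep)) + 1  # argmin takes the first -> fewest
    return (best, rmsep) if return_curve else best


@dataclass
class WavelengthImportance:
    """Per-wavelength Selectivity Ratio and the location of its maximum."""

    wavelengths: np.ndarray
    sr: np.ndarray

    @property
    def peak_wavelength(self) -> float:
        return float(self.wavelengths[int(np.argmax(self.sr))])


def selectivity_ratio(model: PLSRegressionNIPALS, X,
                      wavelengths=None, floor: float = 1e-12) -> WavelengthImportance:
    """Selectivity Ratio from the target projection of X onto the fitted
    regression vector.

    SR_j = var explained in column j by the target-projection component /
    residual variance of column j (denominator floored at `floor`).
    """
    if not hasattr(model, "coef_"):
        raise RuntimeError("model is not fitted")
    X = np.asarray(X, dtype=float)
    b = model.coef_
    bnorm = np.linalg.norm(b)
    if bnorm <= 0:
        raise ValueError("degenerate (all-zero) regression vector")
    Xc = X - model.x_mean_
    t = Xc @ (b / bnorm)
    tt = t @ t
    if tt <= 0:
        raise ValueError("target-projection scores are identically zero")
    p_tp = Xc.T @ t / tt
    explained = tt * p_tp ** 2                 # column sums of (t p')^2
    residual = (Xc ** 2).sum(axis=0) - explained
    sr = explained / np.maximum(residual, floor)
    sr = np.clip(sr, 0.0, None)
    if wavelengths is None:
        wavelengths = np.arange(X.shape[1], dtype=float)
    return WavelengthImportance(np.asarray(wavelengths, float), sr)
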