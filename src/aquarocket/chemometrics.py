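"""Exploratory PCA and latent-variable (PLS) regression for spectral data.

PCA is computed by singular value decomposition of the column-centered value
matrix with a deterministic sign convention (the largest-magnitude element
of each loading vector is made positive).  PLS regression links pretreated
spectra to the leaf-damage index I_LD; calibration performance is the
Pearson correlation of fitted vs observed values ("R-value"), and
cross-validated performance is summarized by the correlation of held-out
predictions plus the standard error of cross-validation

    SECV = sqrt( sum (yhat_cv - y)^2 / (n - 1) ).

Cross-validation defaults to leave-one-out for n <= 40 samples and to 10
shuffled segments (fixed seed) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional
import warnings

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold, LeaveOneOut

from .dataset import SpectralDataset


class ChemometricsError(ValueError):
    pass


@dataclass(frozen=True)
class PCAResult:
    scores: np.ndarray            # n_samples x n_components
    loadings: np.ndarray          # n_wavelengths x n_components
    explained_variance_pct: np.ndarray
    mean: np.ndarray              # column means removed before the SVD
    wavelengths: np.ndarray

    def scores_frame(self, samples=None) -> pd.DataFrame:
        cols = [f"PC{i+1}" for i in range(self.scores.shape[1])]
        df = pd.DataFrame(self.scores, columns=cols)
        if samples is not None:
            df.insert(0, "treatment", [s.treatment for s in samples])
            df.insert(1, "day", [s.day for s in samples])
        return df

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i+1}" for i in range(self.loadings.shape[1])]
        df = pd.DataFrame(self.loadings, columns=cols)
        df.insert(0, "wavelength", self.wavelengths)
        return df


@dataclass(frozen=True)
class PLSResult:
    n_components: int
    coefficients: np.ndarray      # per-wavelength regression vector
    intercept: float
    r_cal: float
    r_cv: float
    secv: float
    factor_loadings: np.ndarray   # n_wavelengths x n_components
    cv_scheme: str
    fitted: np.ndarray
    cv_predictions: np.ndarray
    wavelengths: np.ndarray

    def metrics(self) -> dict:
        return {
            "n_components": self.n_components,
            "r_cal": self.r_cal,
            "r_cv": self.r_cv,
            "secv": self.secv,
            "cv_scheme": self.cv_scheme,
        }


def _as_matrix(ds) -> np.ndarray:
    if isinstance(ds, SpectralDataset):
        return ds.values
    return np.asarray(ds, dtype=float)


def _wavelengths(ds, X) -> np.ndarray:
    if isinstance(ds, SpectralDataset):
        return ds.wavelengths
    return np.arange(X.shape[1], dtype=float)


def fit_pca(ds, n_components: int) -> PCAResult:
    """PCA of the column-centered matrix via SVD.

    ``ds`` may be a :class:`SpectralDataset` or a plain matrix (rows =
    samples).  Explained variance percentages refer to the total variance of
    the centered data.
    """
    X = _as_matrix(ds)
    n, p = X.shape
    if n < 2:
        raise ChemometricsError("PCA needs at least 2 samples")
    if not 1 <= n_components <= min(n - 1, p):
        raise ChemometricsError(
            f"n_components={n_components} must be in [1, {min(n - 1, p)}]"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|.| element of each loading made positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    var = s**2
    total = var.sum()
    pct = 100.0 * var / total if total > 0 else np.zeros_like(var)
    k = n_components
    return PCAResult(
        scores=U[:, :k] * s[:k],
        loadings=Vt[:k].T,
        explained_variance_pct=pct[:k],
        mean=mean,
        wavelengths=_wavelengths(ds, X),
    )


def _default_cv(n: int, seed: int = 0):
    if n <= 40:
        return LeaveOneOut(), "leave-one-out"
    return KFold(n_splits=10, shuffle=True, random_state=seed), "10-fold (shuffled, fixed seed)"


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def cv_predict(X: np.ndarray, y: np.ndarray, n_components: int, cv) -> np.ndarray:
    """Held-out PLS predictions for every sample under the CV splitter."""
    yhat = np.empty_like(y, dtype=float)
    for train, test in cv.split(X):
        k = min(n_components, len(train) - 1, X.shape[1])
        model = PLSRegression(n_components=k, scale=False)
        model.fit(X[train], y[train])
        yhat[test] = model.predict(X[test]).ravel()
    return yhat


def fit_pls(ds, y, n_components: int, cv=None, seed: int = 0) -> PLSResult:
    """PLS regression of ``y`` (e.g. I_LD %) on spectra.

    ``cv`` may be any scikit-learn splitter; by default leave-one-out for
    n <= 40 and seeded 10-fold otherwise.  ``r_cal`` / ``r_cv`` are Pearson
    correlations of fitted / held-out predictions vs observations.
    """
    X = _as_matrix(ds)
    y = np.asarray(y, dtype=float).ravel()
    if y.size != X.shape[0]:
        raise ChemometricsError(
            f"y length {y.size} does not match {X.shape[0]} spectra"
        )
    if np.ptp(y) == 0:
        raise ChemometricsError("response y is constant; PLS undefined")
    if n_components < 1:
        raise ChemometricsError("n_components must be >= 1")
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    scheme = None
    if cv is None:
        cv, scheme = _default_cv(X.shape[0], seed)
    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(X, y)
    fitted = model.predict(X).ravel()
    yhat_cv = cv_predict(X, y, n_components, cv)
    r_cal = _pearson(fitted, y)
    r_cv = _pearson(yhat_cv, y)
    secv = float(np.sqrt(np.sum((yhat_cv - y) ** 2) / (y.size - 1)))
    if r_cv > r_cal + 1e-9:
        warnings.warn(
            f"cross-validated R ({r_cv:.3f}) exceeds calibration R ({r_cal:.3f}); "
            "check the validation scheme",
            RuntimeWarning,
            stacklevel=2,
        )
    return PLSResult(
        n_components=n_components,
        coefficients=np.asarray(model.coef_).reshape(-1),
        intercept=float(np.asarray(model.intercept_).ravel()[0]),
        r_cal=r_cal,
        r_cv=r_cv,
        secv=secv,
        factor_loadings=model.x_loadings_,
        cv_scheme=scheme or type(cv).__name__,
        fitted=fitted,
        cv_predictions=yhat_cv,
        wavelengths=_wavelengths(ds, X),
    )


def cross_validate(ds, y, max_components: int, cv=None, seed: int = 0) -> pd.DataFrame:
    """SECV/R_cv per component count, with a one-standard-error pick.

    Returns a DataFrame with columns ``n_components, r_cv, secv,
    recommended`` where the recommended count is the smallest one whose SECV
    is within one standard error of the minimum (parsimony rule).
    """
    X = _as_matrix(ds)
    y = np.asarray(y, dtype=float).ravel()
    if max_components < 1:
        raise ChemometricsError("max_components must be >= 1")
    max_components = min(max_components, X.shape[0] - 2, X.shape[1])
    if cv is None:
        cv, _ = _default_cv(X.shape[0], seed)
    rows = []
    sq_errors = {}
    for k in range(1, max_components + 1):
        yhat = cv_predict(X, y, k, cv)
        sq = (yhat - y) ** 2
        sq_errors[k] = sq
        rows.append(
            {
                "n_components": k,
                "r_cv": _pearson(yhat, y),
                "secv": float(np.sqrt(sq.sum() / (y.size - 1))),
            }
        )
    table = pd.DataFrame(rows)
    best = int(table.loc[table["secv"].idxmin(), "n_components"])
    sq_best = sq_errors[best]
    se_mse = sq_best.std(ddof=1) / np.sqrt(sq_best.size)
    threshold = np.sqrt(sq_best.mean() * (y.size / (y.size - 1)) + se_mse)
    recommended = int(table.loc[table["secv"] <= threshold, "n_components"].min())
    table["recommended"] = table["n_components"] == recommended
    return table
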