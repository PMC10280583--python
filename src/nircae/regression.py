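"""Regression families: MLR on latent variables, and PLSR/PCR baselines.

All three estimators expose the same affine predictor surface
(``coef_`` in input-feature space, ``intercept_``, ``predict``) so a fitted
model serializes to a flat JSON document regardless of family.

* :class:`LatentMLR` — ordinary least squares with intercept, the
  regression applied to autoencoder latent variables. Requires more
  samples than features and a full-rank design; collinear columns are
  named in the error.
* :class:`PLSRegressor` — single-response partial least squares (NIPALS,
  via scikit-learn), X and y centered on calibration means.
* :class:`PCRegressor` — principal component regression: PCA of centered
  X (full SVD, components by decreasing singular value), then OLS of
  centered y on the leading scores.

Component counts for PLSR/PCR are chosen by seeded 5-fold cross-validated
RMSE over k = 1..10 (:func:`select_components_cv`); folds are shared
across k and across families so comparisons are paired.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y


class _AffineModel(BaseEstimator, RegressorMixin):
    """Shared affine-predictor surface: yhat = X @ coef_ + intercept_."""

    family: str = ""

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return X @ self.coef_ + self.intercept_

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        d = {
            "family": self.family,
            "coefficients": self.coef_.tolist(),
            "intercept": float(self.intercept_),
            "n_components": getattr(self, "n_components", None),
            "x_center": getattr(self, "x_mean_", np.zeros(0)).tolist(),
            "y_center": float(getattr(self, "y_mean_", 0.0)),
        }
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def load_model(path) -> "_AffineModel":
    """Rebuild any serialized affine regression model from JSON."""
    with open(path) as fh:
        d = json.load(fh)
    cls = {"mlr": LatentMLR, "plsr": PLSRegressor, "pcr": PCRegressor}[d["family"]]
    model = cls() if d["n_components"] is None else cls(d["n_components"])
    model.coef_ = np.asarray(d["coefficients"], dtype=float)
    model.intercept_ = float(d["intercept"])
    model.x_mean_ = np.asarray(d["x_center"], dtype=float)
    model.y_mean_ = float(d["y_center"])
    return model


class LatentMLR(_AffineModel):
    """Ordinary least squares with intercept on latent variables.

    Requires n_samples > n_features (with 60 calibration samples and 32
    latents this always holds in the intended use) and a full-rank design;
    a rank-deficient design raises with the collinear columns identified
    unless ``allow_rank_deficient=True`` requests the minimum-norm fit.
    """

    family = "mlr"

    def __init__(self, allow_rank_deficient: bool = False):
        self.allow_rank_deficient = allow_rank_deficient

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        n, p = X.shape
        if n <= p:
            raise ValueError(
                f"MLR needs more samples than features (n={n}, p={p}); "
                "reduce dimensionality first"
            )
        design = np.column_stack([np.ones(n), X])
        rank = np.linalg.matrix_rank(design)
        if rank < p + 1 and not self.allow_rank_deficient:
            # identify offending columns via pivoted QR: small trailing
            # R diagonals mark (near-)dependent columns
            from scipy.linalg import qr
            _, R, piv = qr(design, mode="economic", pivoting=True)
            diag = np.abs(np.diag(R))
            bad = sorted(int(c) - 1 for c in piv[rank:] if c > 0)
            raise np.linalg.LinAlgError(
                f"rank-deficient design (rank {rank} < {p + 1}); "
                f"collinear feature columns: {bad}"
            )
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.n_features_in_ = p
        return self


class PLSRegressor(_AffineModel):
    """Single-response PLS (NIPALS) returned as an affine predictor.

    Attributes after fit: ``x_scores_`` (orthogonal component scores),
    ``x_mean_``, ``y_mean_`` (calibration centering), ``coef_``,
    ``intercept_``.
    """

    family = "plsr"

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if np.std(y) == 0:
            raise ValueError("target has zero variance")
        k = self.n_components
        if not 1 <= k <= min(X.shape[0] - 1, X.shape[1]):
            raise ValueError(f"n_components={k} out of range for {X.shape}")
        pls = PLSRegression(n_components=k, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls.fit(X, y)
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(np.mean(y))
        self.x_scores_ = pls.x_scores_
        self.coef_ = pls.coef_.ravel()
        self.intercept_ = float(self.y_mean_ - self.x_mean_ @ self.coef_)
        self.n_features_in_ = X.shape[1]
        return self


class PCRegressor(_AffineModel):
    """Principal component regression as an affine predictor."""

    family = "pcr"

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if np.std(y) == 0:
            raise ValueError("target has zero variance")
        k = self.n_components
        if not 1 <= k <= min(X.shape[0] - 1, X.shape[1]):
            raise ValueError(f"n_components={k} out of range for {X.shape}")
        pca = PCA(n_components=k, svd_solver="full")
        scores = pca.fit_transform(X)  # PCA centers X internally
        yc = y - y.mean()
        gamma, *_ = np.linalg.lstsq(scores, yc, rcond=None)
        self.x_mean_ = pca.mean_
        self.y_mean_ = float(y.mean())
        self.scores_ = scores
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.coef_ = pca.components_.T @ gamma
        self.intercept_ = float(self.y_mean_ - self.x_mean_ @ self.coef_)
        self.n_features_in_ = X.shape[1]
        return self


FAMILIES = {"mlr": LatentMLR, "plsr": PLSRegressor, "pcr": PCRegressor}


@dataclass
class CVResult:
    """Cross-validation trace for component selection."""

    rmse_per_k: dict[int, float]
    selected: int
    seed: int
    family: str

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_components": list(self.rmse_per_k),
             "cv_rmse": list(self.rmse_per_k.values())}
        )


def select_components_cv(X, y, family: str, k_max: int = 10, folds: int = 5,
                         seed: int = 0) -> CVResult:
    """Pick the PLSR/PCR component count by k-fold cross-validated RMSE.

    Fold assignment is shuffled with the given seed and reused for every
    candidate k (paired comparison). The selected count minimizes the mean
    held-out RMSE; ties break toward the smaller count. ``k_max`` is
    clipped (with a warning) when it exceeds what the smallest training
    fold supports.
    """
    X, y = check_X_y(X, y, y_numeric=True)
    if family not in ("plsr", "pcr"):
        raise ValueError("family must be 'plsr' or 'pcr'")
    if np.std(y) == 0:
        raise ValueError("target has zero variance")
    n = X.shape[0]
    if n < folds:
        raise ValueError(f"need at least {folds} samples, got {n}")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    min_train = min(len(tr) for tr, _ in splits)
    limit = min(min_train - 1, X.shape[1])
    if k_max > limit:
        warnings.warn(
            f"k_max={k_max} clipped to {limit} (smallest training fold)",
            stacklevel=2,
        )
        k_max = limit
    cls = FAMILIES[family]
    rmse_per_k: dict[int, float] = {}
    for k in range(1, k_max + 1):
        errs = []
        for tr, te in splits:
            model = cls(n_components=k).fit(X[tr], y[tr])
            resid = y[te] - model.predict(X[te])
            errs.append(np.sqrt(np.mean(resid ** 2)))
        rmse_per_k[k] = float(np.mean(errs))
    selected = min(rmse_per_k, key=lambda k: (rmse_per_k[k], k))
    return CVResult(rmse_per_k=rmse_per_k, selected=selected, seed=seed,
                    family=family)


def fit_mlr(latents, targets, **kwargs) -> LatentMLR:
    """Functional wrapper: OLS of a target on the latent matrix."""
    return LatentMLR(**kwargs).fit(latents, targets)


def fit_plsr(X, y, n_components: int) -> PLSRegressor:
    return PLSRegressor(n_components=n_components).fit(X, y)


def fit_pcr(X, y, n_components: int) -> PCRegressor:
    return PCRegressor(n_components=n_components).fit(X, y)
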