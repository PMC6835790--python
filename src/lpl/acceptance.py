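"""Product acceptance maps: regression landscapes over the consumer map.

One landscape models one evaluation — a product's overall liking, or a
product x attribute JAR perception — as a function f of the 2-D map
coordinates, fitted to the n training pairs (x_i*, g_i).  Two
regressors are supported:

* quadratic response surface (ordinary least squares),
  f = a0 + a1 d1 + a2 d2 + a3 d1^2 + a4 d2^2 + a5 d1 d2;
* epsilon-insensitive support-vector regression with Gaussian (RBF)
  kernel.

Fit quality is the percentage error, 100 * MAE / n_points, where MAE is
the mean absolute training residual and n_points counts the categories
of the evaluation's scale (9 hedonic, 5 JAR).  It is a descriptive
training-fit measure, not a generalization estimate: no holdout is
involved, by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.svm import SVR

from .data import ConfigurationError, RankError, ScaleSpec
from .density import DensityField, GridSpec
from .embed import Embedding2D


def _design(X: np.ndarray) -> np.ndarray:
    d1, d2 = X[:, 0], X[:, 1]
    return np.column_stack([np.ones_like(d1), d1, d2, d1**2, d2**2, d1 * d2])


class QuadraticSurface(RegressorMixin, BaseEstimator):
    """Quadratic acceptance landscape fitted by ordinary least squares.

    Fitted attribute ``alpha_`` holds the six coefficients
    (a0, a1 d1, a2 d2, a3 d1^2, a4 d2^2, a5 d1 d2).
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ConfigurationError("coordinates must be n x 2")
        if X.shape[0] < 6:
            raise RankError(
                f"quadratic surface needs >= 6 points, got {X.shape[0]}"
            )
        A = _design(X)
        rank = np.linalg.matrix_rank(A)
        if rank < 6:
            raise RankError(
                f"design matrix rank {rank} < 6 (collinear or degenerate coordinates)"
            )
        self.alpha_, *_ = np.linalg.lstsq(A, y, rcond=None)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return _design(X) @ self.alpha_


def default_rbf_gamma(X: np.ndarray) -> float:
    """RBF width gamma = 1 / (2 * mean pairwise squared distance)."""
    X = np.asarray(X, dtype=float)
    sq = pdist(X, "sqeuclidean")
    mean_sq = float(sq.mean()) if sq.size else 1.0
    if mean_sq <= 0:
        mean_sq = 1.0
    return 1.0 / (2.0 * mean_sq)


class SVMSurface(RegressorMixin, BaseEstimator):
    """RBF support-vector-regression acceptance landscape.

    Hyperparameter defaults: C = 1, epsilon = 0.1, gamma = "scale" (the
    sklearn convention, 1 / (n_features * var(X)); the paper's fits
    rely on the library default).  ``gamma`` also accepts "auto", a
    positive float, or "pairwise" for 1 / (2 * mean pairwise squared
    distance of the coordinates).  Deterministic given inputs and
    hyperparameters.
    """

    def __init__(self, C: float = 1.0, epsilon: float = 0.1, gamma="scale"):
        self.C = C
        self.epsilon = epsilon
        self.gamma = gamma

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        bad_gamma = (
            isinstance(self.gamma, (int, float)) and self.gamma <= 0
        ) or (isinstance(self.gamma, str) and self.gamma not in ("scale", "auto", "pairwise"))
        if self.C <= 0 or self.epsilon < 0 or bad_gamma:
            raise ConfigurationError(
                f"invalid SVR hyperparameters C={self.C}, epsilon={self.epsilon}, gamma={self.gamma}"
            )
        if X.shape[0] < 2:
            raise ConfigurationError("SVR needs at least 2 points")
        self.gamma_ = default_rbf_gamma(X) if self.gamma == "pairwise" else self.gamma
        self._svr = SVR(kernel="rbf", C=self.C, epsilon=self.epsilon, gamma=self.gamma_)
        self._svr.fit(X, y)
        return self

    def predict(self, X):
        return self._svr.predict(np.asarray(X, dtype=float))


def svm_grid_search(
    X,
    y,
    C_grid=(0.1, 1.0, 10.0),
    epsilon_grid=(0.05, 0.1, 0.5),
) -> SVMSurface:
    """Small deterministic grid search on training MAE (off by default
    in every pipeline: the shipped defaults keep runs reproducible)."""
    best, best_mae = None, np.inf
    for C in C_grid:
        for eps in epsilon_grid:
            model = SVMSurface(C=C, epsilon=eps).fit(X, y)
            mae = float(np.abs(model.predict(X) - np.asarray(y, dtype=float)).mean())
            if mae < best_mae - 1e-12:
                best, best_mae = model, mae
    return best


def _training_coords(model_or_coords) -> np.ndarray:
    if isinstance(model_or_coords, Embedding2D):
        return model_or_coords.coords
    return np.asarray(model_or_coords, dtype=float)


def fit_quadratic(embedding, grades) -> QuadraticSurface:
    """OLS quadratic landscape for one evaluation on a consumer map."""
    return QuadraticSurface().fit(_training_coords(embedding), grades)


def fit_svm(embedding, grades, **hyperparams) -> SVMSurface:
    """RBF-SVR landscape for one evaluation on a consumer map."""
    return SVMSurface(**hyperparams).fit(_training_coords(embedding), grades)


def percentage_error(model, embedding, grades, scale: ScaleSpec, denominator: str = "n_points") -> float:
    """Training percentage error: 100 * MAE / number of scale points.

    ``denominator="range"`` divides by the scale span instead (a
    non-default variant for sensitivity checks).
    """
    coords = _training_coords(embedding)
    g = np.asarray(grades, dtype=float)
    if g.shape[0] != coords.shape[0]:
        raise ConfigurationError("grades and coordinates disagree in length")
    if not all(scale.contains(v) for v in g):
        raise ConfigurationError(
            f"grades fall outside the {scale.name} scale [{scale.min_value}, {scale.max_value}]"
        )
    mae = float(np.abs(model.predict(coords) - g).mean())
    if denominator == "n_points":
        denom = scale.n_points
    elif denominator == "range":
        denom = scale.max_value - scale.min_value
    else:
        raise ConfigurationError(f"unknown denominator rule {denominator!r}")
    return 100.0 * mae / denom


@dataclass(frozen=True)
class AcceptanceSurface:
    """A fitted landscape evaluated on the shared map grid."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    values: np.ndarray  # ny x nx fitted f(x)
    regressor: str  # QUA | SVM
    evaluation_id: tuple[str, str]  # (product, measure)
    percentage_error: float
    grades: np.ndarray  # the n training grades

    def __post_init__(self) -> None:
        if not (0.0 <= self.percentage_error <= 100.0):
            raise ConfigurationError("percentage error must lie in [0, 100]")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("non-finite landscape values")


def evaluate_surface(
    model,
    grid,
    evaluation_id: tuple[str, str],
    embedding,
    grades,
    scale: ScaleSpec,
) -> AcceptanceSurface:
    """Evaluate a fitted landscape on a grid shared with the density map."""
    if isinstance(grid, DensityField):
        gx, gy = grid.grid_x, grid.grid_y
    elif isinstance(grid, GridSpec):
        gx, gy = grid.axes()
    else:
        gx, gy = (np.asarray(g, dtype=float) for g in grid)
    XX, YY = np.meshgrid(gx, gy)
    vals = model.predict(np.column_stack([XX.ravel(), YY.ravel()])).reshape(len(gy), len(gx))
    err = percentage_error(model, embedding, grades, scale)
    name = "QUA" if isinstance(model, QuadraticSurface) else "SVM"
    return AcceptanceSurface(
        gx, gy, vals, name, tuple(evaluation_id), err, np.asarray(grades, dtype=float)
    )
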