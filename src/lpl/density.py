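"""Consumer-distribution map: bivariate Gaussian KDE on a shared grid.

The density at a map point x is a sum of Gaussian kernels centered on
the n consumer positions x_i*,

    p(x) = 1 / (2 pi n h^2) * sum_i exp(-||x - x_i*||^2 / (2 h^2)),

with a single bandwidth h from the bivariate Scott rule h = n^(-1/6),
applied to the raw (unstandardized) map coordinates.  A legacy variant
that divides the exponent by 2h instead of 2h^2 is available behind
``as_printed=True``; it is not a normalized density and exists only for
fidelity comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .data import DegenerateInputError, LPLError
from .embed import Embedding2D


class DomainError(LPLError):
    """Argument outside the operation's mathematical domain."""


class DegenerateFieldError(LPLError):
    """Field has no structure to extract (e.g. identically zero)."""


@dataclass(frozen=True)
class GridSpec:
    """Rectangular evaluation grid shared by density and acceptance maps."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    num: int = 200

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.linspace(self.x_min, self.x_max, self.num),
            np.linspace(self.y_min, self.y_max, self.num),
        )

    @classmethod
    def from_points(cls, coords: np.ndarray, expand: float = 0.15, num: int = 200) -> "GridSpec":
        """Bounding box of the points expanded by ``expand`` per side."""
        coords = np.asarray(coords, dtype=float)
        lo = coords.min(axis=0)
        hi = coords.max(axis=0)
        span = np.maximum(hi - lo, 1e-9)
        lo = lo - expand * span
        hi = hi + expand * span
        return cls(lo[0], hi[0], lo[1], hi[1], num)


@dataclass(frozen=True)
class DensityField:
    """Gridded KDE estimate of the consumer distribution."""

    grid_x: np.ndarray  # monotone, length nx
    grid_y: np.ndarray  # monotone, length ny
    values: np.ndarray  # ny x nx, p(x) >= 0
    bandwidth_h: float
    n_consumers: int

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.grid_y), len(self.grid_x)):
            raise DegenerateFieldError("values shape must be (ny, nx)")
        if (self.values < 0).any():
            raise DegenerateFieldError("density must be non-negative")
        if self.bandwidth_h <= 0:
            raise DomainError("bandwidth must be positive")

    def integral(self) -> float:
        """Trapezoid-rule integral of the field over its grid."""
        return float(np.trapezoid(np.trapezoid(self.values, self.grid_x, axis=1), self.grid_y))


def scott_bandwidth(n: int) -> float:
    """Bivariate Scott-rule bandwidth h = n^(-1/6)."""
    if n < 1:
        raise DomainError(f"need n >= 1 consumers, got {n}")
    return float(n) ** (-1.0 / 6.0)


def _coords_of(embedding) -> np.ndarray:
    if isinstance(embedding, Embedding2D):
        return embedding.coords
    coords = np.asarray(embedding, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise DomainError("expected an Embedding2D or an n x 2 array")
    return coords


class KernelDensityMap(BaseEstimator):
    """Gaussian-kernel density estimator over 2-D consumer coordinates.

    ``bandwidth=None`` selects the Scott rule at fit time.  After
    ``fit``, ``score_samples`` evaluates p(x) at arbitrary points and
    ``evaluate`` produces a :class:`DensityField` on a grid.
    """

    def __init__(self, bandwidth: float | None = None, as_printed: bool = False):
        self.bandwidth = bandwidth
        self.as_printed = as_printed

    def fit(self, X, y=None):
        X = _coords_of(X)
        if X.shape[0] < 1:
            raise DomainError("need at least one consumer")
        self.points_ = X
        self.bandwidth_ = (
            float(self.bandwidth) if self.bandwidth is not None else scott_bandwidth(X.shape[0])
        )
        if self.bandwidth_ <= 0:
            raise DomainError("bandwidth must be positive")
        return self

    def score_samples(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        h = self.bandwidth_
        n = self.points_.shape[0]
        sq = ((X[:, None, :] - self.points_[None, :, :]) ** 2).sum(axis=2)
        denom = 2.0 * h if self.as_printed else 2.0 * h * h
        return np.exp(-sq / denom).sum(axis=1) / (2.0 * np.pi * n * h * h)

    def evaluate(self, grid: GridSpec) -> DensityField:
        gx, gy = grid.axes()
        XX, YY = np.meshgrid(gx, gy)
        pts = np.column_stack([XX.ravel(), YY.ravel()])
        vals = self.score_samples(pts).reshape(len(gy), len(gx))
        return DensityField(gx, gy, vals, self.bandwidth_, self.points_.shape[0])


def estimate_density(
    embedding,
    grid: GridSpec | None = None,
    h: float | None = None,
    as_printed: bool = False,
) -> DensityField:
    """KDE consumer-distribution map on a grid (default: 200 x 200 over
    the consumer bounding box expanded by 15% per side)."""
    coords = _coords_of(embedding)
    est = KernelDensityMap(bandwidth=h, as_printed=as_printed).fit(coords)
    if grid is None:
        grid = GridSpec.from_points(coords)
    return est.evaluate(grid)


def density_contours(field: DensityField, n_levels: int = 6) -> np.ndarray:
    """Evenly spaced positive contour levels in (0, max p].

    Levels are max * k / (n_levels + 1) for k = 1..n_levels, so a single
    level sits at half the peak.
    """
    if n_levels < 1:
        raise DomainError("n_levels must be >= 1")
    peak = float(field.values.max())
    if peak <= 0:
        raise DegenerateFieldError("flat zero density field has no contours")
    return peak * np.arange(1, n_levels + 1) / (n_levels + 1)
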