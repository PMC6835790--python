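"""Consumer maps: project consumer vectors from R^d to the plane.

Three techniques are offered, all exposed both as sklearn-style
transformers and as thin ``embed_*`` functions returning an
:class:`Embedding2D`:

* ``PCAEmbedding`` — scores on the first two principal components of
  the column-centered consumer matrix (any data mode).
* ``IPMEmbedding`` — the internal-preference-mapping variant: PCA is
  run on the products-by-consumers overall-liking matrix (consumers as
  variables); products become points (their scores), and each
  consumer's map position is its loading on the first two components
  scaled by the variance of the product scores on that component.
* ``MDSEmbedding`` — metric multidimensional scaling of the Euclidean
  distance matrix by SMACOF majorization, initialized from classical
  (Torgerson) scaling.  Reported fit is Kruskal stress-1,
  sqrt(sum_{i<j} (d_ij - dhat_ij)^2 / sum_{i<j} d_ij^2).

Orientation is made canonical everywhere (principal axes, sign fixed so
the largest-magnitude entry of each axis is positive) so that repeated
runs and figures are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin

from .data import (
    OVERALL_LIKING,
    ConsumerVectors,
    DegenerateInputError,
    EvaluationTable,
    RankError,
    to_vectors,
)


@dataclass(frozen=True)
class Embedding2D:
    """Mapped consumer coordinates plus technique metadata."""

    consumer_ids: tuple[str, ...]
    coords: np.ndarray  # n x 2
    technique: str  # IPM | PCA | MDS
    data_mode: str  # OL | JAR | OLJAR
    stress: float | None = None  # MDS only (Kruskal stress-1)
    explained_variance: tuple[float, float] | None = None  # PCA / IPM
    product_coords: np.ndarray | None = None  # IPM only, P x 2
    product_ids: tuple[str, ...] | None = None  # IPM only
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coords.shape != (len(self.consumer_ids), 2):
            raise DegenerateInputError("coords must be n x 2")
        if not np.all(np.isfinite(self.coords)):
            raise DegenerateInputError("non-finite embedding coordinates")
        if self.stress is not None and self.stress < 0:
            raise DegenerateInputError("stress must be >= 0")

    @property
    def n(self) -> int:
        return self.coords.shape[0]


def _fix_signs(components: np.ndarray, *coupled: np.ndarray) -> tuple[np.ndarray, ...]:
    """Flip each component so its largest-|entry| is positive.

    ``coupled`` arrays (scores, loadings) sharing the component axis on
    their last dimension are flipped consistently.
    """
    comp = components.copy()
    outs = [c.copy() for c in coupled]
    for k in range(comp.shape[0]):
        j = int(np.argmax(np.abs(comp[k])))
        if comp[k, j] < 0:
            comp[k] *= -1
            for o in outs:
                o[:, k] *= -1
    return (comp, *outs)


class PCAEmbedding(TransformerMixin, BaseEstimator):
    """First-two-principal-component scores of the consumer matrix.

    Columns are centered (optionally standardized); the sign of each
    component is fixed so the largest-|loading| entry is positive.
    """

    def __init__(self, standardize: bool = False):
        self.standardize = standardize

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        if n < 3 or d < 2:
            raise DegenerateInputError(f"PCA needs n >= 3 and d >= 2, got {X.shape}")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        if self.standardize:
            scale = Xc.std(axis=0, ddof=1)
            scale[scale == 0] = 1.0
            Xc = Xc / scale
            self.scale_ = scale
        else:
            self.scale_ = np.ones(d)
        if np.allclose(Xc, 0):
            raise DegenerateInputError("zero-variance data: PCA undefined")
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        Vt, U = _fix_signs(Vt, U)
        self.components_ = Vt[:2]
        var = s**2 / (n - 1)
        total = var.sum()
        self.explained_variance_ratio_ = tuple(var[:2] / total)
        self.singular_values_ = s[:2]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return ((X - self.mean_) / self.scale_) @ self.components_.T

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


class IPMEmbedding(TransformerMixin, BaseEstimator):
    """Internal-preference-mapping consumer coordinates from OL grades.

    Fit on the n x P consumers-by-products overall-liking matrix.  PCA
    is applied to its transpose (P observations, n consumer variables,
    columns centered): ``product_coords_`` are the product scores on
    the first two components, and each consumer's position is its
    loading scaled by the per-component variance of the product scores.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, P = X.shape
        if P < 3:
            raise RankError(f"IPM needs at least 3 products, got {P}")
        M = X.T  # P x n, consumers as variables
        Mc = M - M.mean(axis=0)
        if np.allclose(Mc, 0):
            raise DegenerateInputError("zero-variance grades: IPM undefined")
        U, s, Vt = np.linalg.svd(Mc, full_matrices=False)
        scores = U * s  # product scores, P x r
        Vt, scores = _fix_signs(Vt, scores)
        loadings = Vt[:2].T  # n x 2 consumer loadings
        self.product_coords_ = scores[:, :2]
        score_var = self.product_coords_.var(axis=0, ddof=1)
        self.score_variance_ = score_var
        self.embedding_ = loadings * score_var
        var = s**2 / max(P - 1, 1)
        self.explained_variance_ratio_ = tuple(var[:2] / var.sum())
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_

    def transform(self, X):
        # IPM positions exist only for the fitted panel.
        return self.embedding_


def _classical_scaling(D: np.ndarray, k: int = 2) -> np.ndarray:
    """Torgerson classical scaling of a distance matrix to k dims."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order[:k]], V[:, order[:k]]
    return V * np.sqrt(np.clip(w, 0, None))


def kruskal_stress(D: np.ndarray, coords: np.ndarray) -> float:
    """Normalized stress-1 between original and embedded distances."""
    Dhat = squareform(pdist(coords))
    iu = np.triu_indices_from(D, k=1)
    denom = (D[iu] ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((D[iu] - Dhat[iu]) ** 2).sum() / denom))


class MDSEmbedding(TransformerMixin, BaseEstimator):
    """Metric MDS by SMACOF majorization with classical-scaling start.

    The Guttman transform decreases the raw stress
    sum_{i<j} (d_ij - dhat_ij)^2 monotonically; iteration stops when the
    relative decrease falls below ``tol`` or after ``max_iter`` rounds.
    The seed only matters for degenerate (tied / zero-distance) starts.
    Fitted attributes: ``embedding_``, ``stress_`` (Kruskal stress-1),
    ``stress_history_`` (raw stress per iteration).
    """

    def __init__(self, max_iter: int = 300, tol: float = 1e-9, seed: int = 0):
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n < 3:
            raise DegenerateInputError(f"MDS needs n >= 3, got {n}")
        D = squareform(pdist(X))
        if np.allclose(D, 0):
            raise DegenerateInputError("all consumer vectors identical: MDS undefined")
        coords = _classical_scaling(D, 2)
        if np.allclose(coords.std(axis=0), 0):
            rng = np.random.default_rng(self.seed)
            coords = coords + rng.normal(0, 1e-6, coords.shape)
        history = []
        prev = self._raw_stress(D, coords)
        history.append(prev)
        for _ in range(self.max_iter):
            coords = self._guttman(D, coords)
            cur = self._raw_stress(D, coords)
            history.append(cur)
            if prev - cur <= self.tol * max(prev, 1.0):
                break
            prev = cur
        coords = self._canonical_orientation(coords)
        self.embedding_ = coords
        self.stress_history_ = np.array(history)
        self.stress_ = kruskal_stress(D, coords)
        return self

    @staticmethod
    def _raw_stress(D: np.ndarray, coords: np.ndarray) -> float:
        Dhat = squareform(pdist(coords))
        iu = np.triu_indices_from(D, k=1)
        return float(((D[iu] - Dhat[iu]) ** 2).sum())

    @staticmethod
    def _guttman(D: np.ndarray, coords: np.ndarray) -> np.ndarray:
        n = D.shape[0]
        Dhat = squareform(pdist(coords))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(Dhat > 0, D / Dhat, 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        return B @ coords / n

    @staticmethod
    def _canonical_orientation(coords: np.ndarray) -> np.ndarray:
        centered = coords - coords.mean(axis=0)
        U, s, Vt = np.linalg.svd(centered, full_matrices=False)
        rotated = centered @ Vt.T
        for k in range(rotated.shape[1]):
            j = int(np.argmax(np.abs(rotated[:, k])))
            if rotated[j, k] < 0:
                rotated[:, k] *= -1
        return rotated

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_

    def transform(self, X):
        return self.embedding_


# -- functional surface ----------------------------------------------------

def embed_pca(vectors: ConsumerVectors, standardize: bool = False) -> Embedding2D:
    """PCA consumer map of flattened consumer vectors."""
    est = PCAEmbedding(standardize=standardize)
    coords = est.fit_transform(vectors.matrix)
    return Embedding2D(
        consumer_ids=vectors.consumer_ids,
        coords=coords,
        technique="PCA",
        data_mode=vectors.data_mode,
        explained_variance=est.explained_variance_ratio_,
        metadata={"standardize": standardize},
    )


def embed_ipm(table: EvaluationTable) -> Embedding2D:
    """Internal-preference-mapping consumer map (overall liking only)."""
    vectors = to_vectors(table, "OL")
    est = IPMEmbedding()
    coords = est.fit_transform(vectors.matrix)
    return Embedding2D(
        consumer_ids=vectors.consumer_ids,
        coords=coords,
        technique="IPM",
        data_mode="OL",
        explained_variance=est.explained_variance_ratio_,
        product_coords=est.product_coords_,
        product_ids=tuple(table.products),
        metadata={"consumer_scaling": "loadings * per-component product-score variance"},
    )


def embed_mds(vectors: ConsumerVectors, seed: int = 0, max_iter: int = 300) -> Embedding2D:
    """Metric-MDS consumer map of flattened consumer vectors."""
    est = MDSEmbedding(seed=seed, max_iter=max_iter)
    coords = est.fit_transform(vectors.matrix)
    return Embedding2D(
        consumer_ids=vectors.consumer_ids,
        coords=coords,
        technique="MDS",
        data_mode=vectors.data_mode,
        stress=est.stress_,
        metadata={"n_iter": len(est.stress_history_) - 1},
    )


def segment_separation(embedding: Embedding2D, segments: dict[str, object]) -> float:
    """Between-centroid distance divided by the larger within-segment spread.

    Spread of a segment is the maximum distance of a member from its own
    centroid; values > 1 mean the two segment clouds do not overlap.
    Defined for exactly two labeled segments.
    """
    labels = np.array([segments[c] for c in embedding.consumer_ids], dtype=object)
    uniq = sorted({l for l in labels if l is not None})
    if len(uniq) != 2:
        raise DegenerateInputError(f"need exactly 2 segments, got {uniq}")
    cents, spreads = [], []
    for u in uniq:
        pts = embedding.coords[labels == u]
        c = pts.mean(axis=0)
        cents.append(c)
        spreads.append(np.linalg.norm(pts - c, axis=1).max())
    return float(np.linalg.norm(cents[0] - cents[1]) / max(max(spreads), 1e-12))
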