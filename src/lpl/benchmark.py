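"""Benchmarking the map/data/regressor combinations, plus the classic
cluster and internal-preference-mapping validation views.

Fourteen method combinations exist: the IPM map (overall liking only)
and the PCA/MDS maps fed with OL, JAR or OLJAR coordinates, each paired
with the quadratic (QUA) or support-vector (SVM) acceptance regressor.
Each combination is scored by its mean percentage error over the
overall-liking evaluations (one per product, 9-point scale), over the
JAR evaluations (one per product x attribute, 5-point scale), and by
the average of the two family means; combinations are ranked ascending
on that average, ties broken by label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .acceptance import QuadraticSurface, SVMSurface, percentage_error
from .data import (
    OVERALL_LIKING,
    ConfigurationError,
    ConsumerVectors,
    DegenerateInputError,
    EvaluationTable,
    scale_for_measure,
    to_vectors,
)
from .embed import Embedding2D, embed_ipm, embed_mds, embed_pca

TECHNIQUES = ("IPM", "PCA", "MDS")
DATA_MODES = ("OL", "JAR", "OLJAR")
REGRESSORS = ("QUA", "SVM")


@dataclass(frozen=True)
class MethodCombo:
    """One map-technique / data-mode / regressor combination."""

    map_technique: str
    data_mode: str
    regressor: str

    def __post_init__(self) -> None:
        if self.map_technique not in TECHNIQUES:
            raise ConfigurationError(f"unknown technique {self.map_technique!r}")
        if self.data_mode not in DATA_MODES:
            raise ConfigurationError(f"unknown data mode {self.data_mode!r}")
        if self.regressor not in REGRESSORS:
            raise ConfigurationError(f"unknown regressor {self.regressor!r}")
        if self.map_technique == "IPM" and self.data_mode != "OL":
            raise ConfigurationError("IPM is defined on overall liking only")

    @property
    def label(self) -> str:
        return f"{self.map_technique}_{self.data_mode}_{self.regressor}"

    @classmethod
    def from_label(cls, label: str) -> "MethodCombo":
        tech, mode, reg = label.upper().split("_")
        return cls(tech, mode, reg)


#: The paper-recommended default pipeline.
DEFAULT_COMBO = MethodCombo("MDS", "OLJAR", "SVM")


def enumerate_combos() -> list[MethodCombo]:
    """All 14 valid combinations in deterministic order."""
    maps = [("IPM", "OL")] + [(t, m) for t in ("PCA", "MDS") for m in DATA_MODES]
    return [MethodCombo(t, m, r) for t, m in maps for r in REGRESSORS]


def make_embedding(
    table: EvaluationTable, technique: str, data_mode: str, seed: int = 0
) -> Embedding2D:
    """Build the consumer map for one technique/data-mode pair."""
    technique = technique.upper()
    if technique == "IPM":
        return embed_ipm(table)
    vectors = to_vectors(table, data_mode)
    if technique == "PCA":
        return embed_pca(vectors)
    if technique == "MDS":
        return embed_mds(vectors, seed=seed)
    raise ConfigurationError(f"unknown technique {technique!r}")


@dataclass(frozen=True)
class BenchmarkResult:
    """Per-combination error summary and ranking."""

    errors: pd.DataFrame  # index label; columns ol_error, jar_error, average
    ranking: tuple[str, ...]  # labels sorted by ascending average error

    def error_of(self, label: str, column: str = "average") -> float:
        return float(self.errors.loc[label, column])


def _make_regressor(name: str):
    return QuadraticSurface() if name == "QUA" else SVMSurface()


def run_benchmark(table: EvaluationTable, seed: int = 0) -> BenchmarkResult:
    """Score all 14 combinations on every evaluation of a panel.

    For each combination the consumer map is built once, then one
    acceptance model is fitted per evaluation (each product's overall
    liking and each product x attribute JAR); errors are averaged per
    evaluation family and overall.  Reproducible bit-for-bit given
    (table, seed).
    """
    if OVERALL_LIKING not in table.measures or not table.attributes:
        raise ConfigurationError("benchmark needs overall liking and >= 1 attribute")
    embeddings: dict[tuple[str, str], Embedding2D] = {}
    rows = {}
    for combo in enumerate_combos():
        key = (combo.map_technique, combo.data_mode)
        if key not in embeddings:
            try:
                embeddings[key] = make_embedding(table, *key, seed=seed)
            except Exception as exc:
                raise type(exc)(f"[{combo.label}] {exc}") from exc
        emb = embeddings[key]
        ol_errs, jar_errs = [], []
        for product in table.products:
            for measure in table.measures:
                grades = table.values_for(product, measure).to_numpy()
                scale = scale_for_measure(measure)
                try:
                    model = _make_regressor(combo.regressor).fit(emb.coords, grades)
                except Exception as exc:
                    raise type(exc)(f"[{combo.label}] {exc}") from exc
                err = percentage_error(model, emb, grades, scale)
                (ol_errs if measure == OVERALL_LIKING else jar_errs).append(err)
        ol = float(np.mean(ol_errs))
        jar = float(np.mean(jar_errs))
        rows[combo.label] = {"ol_error": ol, "jar_error": jar, "average": (ol + jar) / 2.0}
    # stable mergesort over a lexicographically sorted index -> ties break by label
    errors = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    ranking = tuple(errors.sort_values("average", kind="mergesort").index)
    return BenchmarkResult(errors=errors, ranking=ranking)


@dataclass(frozen=True)
class ClusteringResult:
    """Ward hierarchical clustering of consumer vectors."""

    consumer_ids: tuple[str, ...]
    labels: np.ndarray
    chosen_k: int
    linkage_matrix: np.ndarray  # scipy format, for dendrograms
    silhouettes: dict[int, float]  # k -> mean silhouette (empty if k forced)


def cluster_consumers(vectors: ConsumerVectors, k: int | None = None) -> ClusteringResult:
    """Agglomerative Ward/Euclidean clustering of consumer vectors.

    When ``k`` is not given it is chosen to maximize the mean
    silhouette over k in [2, min(8, n-1)].  Identical vectors collapse
    to a single cluster (with a degenerate-distance warning semantics:
    chosen_k = 1).
    """
    X = vectors.matrix
    n = X.shape[0]
    if n < 2:
        raise DegenerateInputError("clustering needs at least 2 consumers")
    if np.allclose(pdist(X), 0):
        return ClusteringResult(
            vectors.consumer_ids,
            np.zeros(n, dtype=int),
            1,
            linkage(X, method="ward"),
            {},
        )
    Z = linkage(X, method="ward")
    sils: dict[int, float] = {}
    if k is None:
        best_k, best_s = 2, -np.inf
        for kk in range(2, min(8, n - 1) + 1):
            lab = AgglomerativeClustering(n_clusters=kk, linkage="ward").fit_predict(X)
            if len(np.unique(lab)) < 2:
                continue
            s = float(silhouette_score(X, lab))
            sils[kk] = s
            if s > best_s + 1e-12:
                best_k, best_s = kk, s
        k = best_k
    labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
    return ClusteringResult(vectors.consumer_ids, labels, k, Z, sils)


def ipm_plot(table: EvaluationTable, ax=None):
    """Classic internal preference map: product points, consumer arrows.

    Arrows point from the origin toward each consumer's loading-scaled
    position; their direction indicates which products that consumer
    prefers and their length grows with the consumer's grade variance.
    """
    import matplotlib.pyplot as plt

    emb = embed_ipm(table)
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 6))
    else:
        fig = ax.figure
    for (x, y) in emb.coords:
        ax.annotate(
            "", xy=(x, y), xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="0.55", lw=0.8),
        )
    px, py = emb.product_coords[:, 0], emb.product_coords[:, 1]
    ax.scatter(px, py, c="crimson", s=60, zorder=3)
    for pid, x, y in zip(emb.product_ids, px, py):
        ax.annotate(pid, (x, y), textcoords="offset points", xytext=(5, 5))
    ev = emb.explained_variance
    ax.set_xlabel(f"PC1 ({ev[0]:.0%})")
    ax.set_ylabel(f"PC2 ({ev[1]:.0%})")
    ax.set_title("Internal preference map")
    ax.axhline(0, color="0.85", lw=0.8)
    ax.axvline(0, color="0.85", lw=0.8)
    return fig
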