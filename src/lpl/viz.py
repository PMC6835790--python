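"""Liking-product-landscape figures.

A landscape figure superimposes three layers on one shared grid:

* the acceptance surface, colored by the evaluation's scale — a
  diverging blue (dislike) to red (like) ramp over [1, 9] for hedonic
  maps; for JAR maps a five-anchor ramp over [-2, +2]: dark blue (far
  too little), blue, green (just about right), yellow, red (far too
  much);
* transparency driven by the consumer density, normalized by its own
  maximum, so empty regions render pure white and the densest point is
  fully opaque, with density contour lines on top;
* the consumer points, each colored by its own grade.

Each figure is annotated with the evaluation's summary number (mean
overall liking, or the percentage of consumers who find the attribute
just about right) and the landscape's percentage error; both are
recomputed from the raw table.  Three grouped analyses are provided:
one map per product for overall liking, one map per measure for a
single product, and one map per product for a single attribute — all
sharing a single embedding so consumer positions coincide across maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LinearSegmentedColormap, Normalize

from .acceptance import AcceptanceSurface, evaluate_surface
from .benchmark import DEFAULT_COMBO, MethodCombo, _make_regressor, make_embedding
from .data import (
    JAR,
    OVERALL_LIKING,
    ConfigurationError,
    EvaluationTable,
    scale_for_measure,
)
from .density import DensityField, GridSpec, density_contours, estimate_density
from .embed import Embedding2D


class CompositionError(ConfigurationError):
    """Layers do not share a grid or refer to different panels."""


#: Diverging hedonic ramp, blue (1, dislike) -> red (9, like).
HEDONIC_CMAP = plt.get_cmap("coolwarm")
HEDONIC_NORM = Normalize(vmin=1, vmax=9)

#: JAR anchor colors at -2, -1, 0, +1, +2.
JAR_ANCHORS = ["#00008b", "#1e6ee6", "#2ca02c", "#ffd500", "#d62728"]
JAR_CMAP = LinearSegmentedColormap.from_list("jar", JAR_ANCHORS)
JAR_NORM = Normalize(vmin=-2, vmax=2)

# deterministic SVG export (byte-identical apart from nothing at all)
matplotlib.rcParams["svg.hashsalt"] = "lpl"


def color_key_for(measure: str) -> str:
    return "hedonic" if measure == OVERALL_LIKING else "jar"


def grade_colormap(color_key: str):
    if color_key == "hedonic":
        return HEDONIC_CMAP, HEDONIC_NORM
    if color_key == "jar":
        return JAR_CMAP, JAR_NORM
    raise ConfigurationError(f"unknown color key {color_key!r}")


def jar_bar(table: EvaluationTable, product: str, attribute: str) -> np.ndarray:
    """Proportions of consumers per JAR category -2..+2 for one evaluation.

    Non-integer (unrounded simulated) ratings count toward their nearest
    category.
    """
    if attribute == OVERALL_LIKING:
        raise ConfigurationError("jar_bar is defined for JAR attributes only")
    vals = table.values_for(product, attribute).to_numpy()
    cats = np.clip(np.rint(vals), JAR.min_value, JAR.max_value).astype(int)
    counts = np.array([(cats == c).sum() for c in range(JAR.min_value, JAR.max_value + 1)])
    return counts / counts.sum()


@dataclass(frozen=True)
class LPLFigure:
    """A composed landscape figure plus its recomputable annotations."""

    figure: plt.Figure
    surface: AcceptanceSurface
    density: DensityField
    embedding: Embedding2D
    color_key: str
    annotations: dict
    title: str

    def save(self, path, **kwargs) -> None:
        meta = kwargs.pop("metadata", {})
        if str(path).endswith(".svg"):
            meta.setdefault("Date", None)  # strip timestamp for reproducibility
        self.figure.savefig(path, metadata=meta, **kwargs)


def compose_lpl(
    surface: AcceptanceSurface,
    density: DensityField,
    table: EvaluationTable,
    embedding: Embedding2D,
    color_key: str | None = None,
    n_contours: int = 6,
) -> LPLFigure:
    """Combine an acceptance surface and a density map into a landscape.

    Per-node opacity is the density normalized by its own maximum, so
    regions without consumers are white and the densest zone is fully
    saturated.
    """
    if not (
        np.array_equal(surface.grid_x, density.grid_x)
        and np.array_equal(surface.grid_y, density.grid_y)
    ):
        raise CompositionError("surface and density must share one grid")
    product, measure = surface.evaluation_id
    grades = table.values_for(product, measure).to_numpy()
    color_key = color_key or color_key_for(measure)
    cmap, norm = grade_colormap(color_key)

    alpha = density.values / max(density.values.max(), 1e-300)
    fig, ax = plt.subplots(figsize=(6, 5.4))
    rgba = cmap(norm(surface.values))
    rgba[..., 3] = alpha
    extent = (surface.grid_x[0], surface.grid_x[-1], surface.grid_y[0], surface.grid_y[-1])
    ax.imshow(rgba, origin="lower", extent=extent, aspect="auto", interpolation="bilinear")
    levels = density_contours(density, n_contours)
    ax.contour(
        density.grid_x, density.grid_y, density.values,
        levels=levels, colors="0.35", linewidths=0.6,
    )
    ax.scatter(
        embedding.coords[:, 0], embedding.coords[:, 1],
        c=grades, cmap=cmap, norm=norm, s=18, edgecolors="black", linewidths=0.3,
    )

    annotations: dict = {"percentage_error": surface.percentage_error}
    if color_key == "hedonic":
        annotations["mean_grade"] = float(grades.mean())
        note = f"mean OL = {annotations['mean_grade']:.2f}"
    else:
        props = jar_bar(table, product, measure)
        annotations["jar_percent"] = float(props[2] * 100.0)
        annotations["jar_proportions"] = tuple(float(p) for p in props)
        note = f"JAR = {annotations['jar_percent']:.1f}%"
        _draw_jar_bar(ax, props)
    title = f"{product} - {measure}"
    ax.set_title(f"{title}   ({note}, err = {surface.percentage_error:.1f}%)", fontsize=10)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    fig.colorbar(plt.cm.ScalarMappable(norm=norm, cmap=cmap), ax=ax, shrink=0.85)
    return LPLFigure(fig, surface, density, embedding, color_key, annotations, title)


def _draw_jar_bar(ax, props: np.ndarray) -> None:
    """Horizontal bar under the map: segment lengths proportional to the
    share of consumers at each JAR category."""
    left = 0.0
    for p, color in zip(props, JAR_ANCHORS):
        ax.annotate(
            "", xy=(left + p, -0.07), xytext=(left, -0.07),
            xycoords="axes fraction", textcoords="axes fraction",
            arrowprops=dict(arrowstyle="-", color=color, lw=6),
            annotation_clip=False,
        )
        left += p


def _shared_map(table: EvaluationTable, combo: MethodCombo, seed: int):
    embedding = make_embedding(table, combo.map_technique, combo.data_mode, seed=seed)
    grid = GridSpec.from_points(embedding.coords)
    density = estimate_density(embedding, grid=grid)
    return embedding, grid, density


def _landscape_for(table, embedding, grid, density, combo, product, measure) -> LPLFigure:
    grades = table.values_for(product, measure).to_numpy()
    scale = scale_for_measure(measure)
    model = _make_regressor(combo.regressor).fit(embedding.coords, grades)
    surface = evaluate_surface(model, grid, (product, measure), embedding, grades, scale)
    return compose_lpl(surface, density, table, embedding)


def overall_liking_analysis(
    table: EvaluationTable, combo: MethodCombo = DEFAULT_COMBO, seed: int = 0
) -> dict[str, LPLFigure]:
    """One overall-liking landscape per product on a shared map."""
    embedding, grid, density = _shared_map(table, combo, seed)
    return {
        p: _landscape_for(table, embedding, grid, density, combo, p, OVERALL_LIKING)
        for p in table.products
    }


def product_analysis(
    table: EvaluationTable, product: str, combo: MethodCombo = DEFAULT_COMBO, seed: int = 0
) -> dict[str, LPLFigure]:
    """Overall liking plus every attribute of one product, shared map."""
    if product not in table.products:
        raise ConfigurationError(f"unknown product {product!r}")
    embedding, grid, density = _shared_map(table, combo, seed)
    measures = [OVERALL_LIKING] + table.attributes if OVERALL_LIKING in table.measures else table.attributes
    return {
        m: _landscape_for(table, embedding, grid, density, combo, product, m)
        for m in measures
    }


def attribute_analysis(
    table: EvaluationTable, attribute: str, combo: MethodCombo = DEFAULT_COMBO, seed: int = 0
) -> dict[str, LPLFigure]:
    """One JAR landscape per product for a single attribute, shared map."""
    if attribute not in table.attributes:
        raise ConfigurationError(f"unknown attribute {attribute!r}")
    embedding, grid, density = _shared_map(table, combo, seed)
    return {
        p: _landscape_for(table, embedding, grid, density, combo, p, attribute)
        for p in table.products
    }
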