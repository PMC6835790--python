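"""Evaluation data model: rating scales, tidy evaluation tables, consumer vectors.

A consumer study rates P products on a 9-point hedonic scale (overall
liking) and on 5-point just-about-right (JAR) scales for A sensory
attributes, coded -2 (far too little) ... 0 (just about right) ... +2
(far too much).  Each consumer therefore contributes a complete block of
P*(A+1) numbers, which downstream mapping steps flatten into a vector
x_i in R^d under one of three data modes:

========  =========================================  =========
mode      columns                                    d
========  =========================================  =========
OL        overall liking per product                 P
JAR       every attribute per product                P*A
OLJAR     both                                       P*(A+1)
========  =========================================  =========

Ordering everywhere is lexicographic (consumers, products, measures;
vector columns are product-major, measure-minor) so every derived matrix
is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

OVERALL_LIKING = "overall_liking"

LONG_COLUMNS = ("consumer_id", "product_id", "measure", "value")


class LPLError(Exception):
    """Base class for domain errors raised by this package."""


class IncompleteDesignError(LPLError):
    """A (consumer, product, measure) cell is missing from the block design."""


class DuplicateCellError(LPLError):
    """A (consumer, product, measure) cell appears more than once."""


class ScaleViolationError(LPLError):
    """A rating falls outside its scale's bounds."""


class ConfigurationError(LPLError):
    """Invalid combination of arguments / modes / measures."""


class DegenerateInputError(LPLError):
    """Input has no usable variation (all points identical, zero variance...)."""


class RankError(LPLError):
    """Design matrix or input does not have the rank the operation needs."""


@dataclass(frozen=True)
class ScaleSpec:
    """An ordinal rating scale with integer category bounds.

    ``n_points`` is the count of scale categories (9 for the hedonic
    scale, 5 for JAR); it is the denominator of the percentage error.
    """

    name: str
    min_value: int
    max_value: int

    def __post_init__(self) -> None:
        if self.max_value <= self.min_value:
            raise ConfigurationError(
                f"scale {self.name!r}: max_value must exceed min_value"
            )

    @property
    def n_points(self) -> int:
        return self.max_value - self.min_value + 1

    def contains(self, value: float) -> bool:
        return self.min_value <= value <= self.max_value


#: 9-point hedonic liking scale (1 = dislike extremely ... 9 = like extremely).
HEDONIC = ScaleSpec("hedonic", 1, 9)
#: 5-point just-about-right scale, signed coding.
JAR = ScaleSpec("jar", -2, 2)

DEFAULT_SCALES = {"hedonic": HEDONIC, "jar": JAR}


def scale_for_measure(measure: str, scales: dict[str, ScaleSpec] | None = None) -> ScaleSpec:
    """Hedonic scale for overall liking, JAR scale for every attribute."""
    scales = scales or DEFAULT_SCALES
    return scales["hedonic"] if measure == OVERALL_LIKING else scales["jar"]


@dataclass(frozen=True)
class ConsumerVectors:
    """Consumers flattened to an n x d matrix under one data mode."""

    consumer_ids: tuple[str, ...]
    matrix: np.ndarray
    data_mode: str
    column_labels: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.consumer_ids), len(self.column_labels)):
            raise ConfigurationError("matrix shape inconsistent with labels")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]


class EvaluationTable:
    """Complete block of consumer x product x measure ratings.

    Wraps a tidy pandas frame with columns ``consumer_id``, ``segment``
    (optional, may be all-NA), ``product_id``, ``measure``, ``value``.
    Construction validates completeness, uniqueness and scale bounds and
    canonicalizes row order lexicographically.
    """

    def __init__(self, data: pd.DataFrame, scales: dict[str, ScaleSpec] | None = None):
        self.scales = dict(scales or DEFAULT_SCALES)
        df = data.copy()
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"missing required columns: {missing}")
        if "segment" not in df.columns:
            df["segment"] = pd.NA
        df["consumer_id"] = df["consumer_id"].astype(str)
        df["product_id"] = df["product_id"].astype(str)
        df["measure"] = df["measure"].astype(str)
        try:
            df["value"] = pd.to_numeric(df["value"])
        except (ValueError, TypeError) as exc:
            raise ScaleViolationError(f"non-numeric value in table: {exc}") from exc
        self._validate(df)
        df = df.sort_values(["consumer_id", "product_id", "measure"], kind="mergesort")
        self._df = df[["consumer_id", "segment", "product_id", "measure", "value"]].reset_index(drop=True)

    def _validate(self, df: pd.DataFrame) -> None:
        dup = df.duplicated(["consumer_id", "product_id", "measure"], keep=False)
        if dup.any():
            cell = df.loc[dup.idxmax(), ["consumer_id", "product_id", "measure"]]
            raise DuplicateCellError(
                f"duplicate cell ({cell.consumer_id}, {cell.product_id}, {cell.measure})"
            )
        consumers = sorted(df["consumer_id"].unique())
        products = sorted(df["product_id"].unique())
        measures = sorted(df["measure"].unique())
        expected = len(consumers) * len(products) * len(measures)
        if len(df) != expected:
            have = set(zip(df["consumer_id"], df["product_id"], df["measure"]))
            for c in consumers:
                for p in products:
                    for m in measures:
                        if (c, p, m) not in have:
                            raise IncompleteDesignError(
                                f"missing cell (consumer={c}, product={p}, measure={m})"
                            )
        for row in df.itertuples():
            spec = scale_for_measure(row.measure, self.scales)
            if not np.isfinite(row.value) or not spec.contains(row.value):
                raise ScaleViolationError(
                    f"row {row.Index}: value {row.value} outside {spec.name} "
                    f"scale [{spec.min_value}, {spec.max_value}] for measure {row.measure!r}"
                )
        seg_counts = df.groupby("consumer_id")["segment"].nunique(dropna=True)
        if (seg_counts > 1).any():
            bad = seg_counts[seg_counts > 1].index[0]
            raise ConfigurationError(f"consumer {bad!r} has conflicting segment labels")

    # -- accessors ---------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def consumers(self) -> list[str]:
        return sorted(self._df["consumer_id"].unique())

    @property
    def products(self) -> list[str]:
        return sorted(self._df["product_id"].unique())

    @property
    def measures(self) -> list[str]:
        return sorted(self._df["measure"].unique())

    @property
    def attributes(self) -> list[str]:
        return [m for m in self.measures if m != OVERALL_LIKING]

    @property
    def segments(self) -> dict[str, object]:
        """consumer_id -> segment label (None when unlabeled)."""
        s = self._df.groupby("consumer_id")["segment"].first()
        return {c: (None if pd.isna(v) else v) for c, v in s.items()}

    def values_for(self, product: str, measure: str) -> pd.Series:
        """Ratings of one evaluation, indexed by consumer in canonical order."""
        sub = self._df[(self._df["product_id"] == product) & (self._df["measure"] == measure)]
        if sub.empty:
            raise ConfigurationError(f"no evaluation ({product!r}, {measure!r}) in table")
        return sub.set_index("consumer_id")["value"].loc[self.consumers]

    def mean(self, product: str, measure: str, segment: object = None) -> float:
        vals = self.values_for(product, measure)
        if segment is not None:
            segs = self.segments
            vals = vals[[c for c in vals.index if segs[c] == segment]]
        return float(vals.mean())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EvaluationTable):
            return NotImplemented
        a, b = self._df, other._df
        if a.shape != b.shape:
            return False
        key = ["consumer_id", "product_id", "measure"]
        if not (a[key].values == b[key].values).all():
            return False
        seg_a = a["segment"].astype("object").where(a["segment"].notna(), None)
        seg_b = b["segment"].astype("object").where(b["segment"].notna(), None)
        return bool(
            np.allclose(a["value"], b["value"]) and (seg_a.values == seg_b.values).all()
        )

    def __len__(self) -> int:
        return len(self._df)

    def __repr__(self) -> str:
        return (
            f"EvaluationTable({len(self.consumers)} consumers x "
            f"{len(self.products)} products x {len(self.measures)} measures)"
        )


def to_vectors(table: EvaluationTable, data_mode: str = "OLJAR") -> ConsumerVectors:
    """Flatten an evaluation table into per-consumer vectors.

    Column order is product-major, measure-minor, both lexicographic, so
    d = P (OL), P*A (JAR) or P*(A+1) (OLJAR).
    """
    data_mode = data_mode.upper()
    if data_mode not in ("OL", "JAR", "OLJAR"):
        raise ConfigurationError(f"unknown data mode {data_mode!r}")
    if data_mode == "OL":
        measures = [OVERALL_LIKING]
        if OVERALL_LIKING not in table.measures:
            raise ConfigurationError("table has no overall_liking measure")
    elif data_mode == "JAR":
        measures = table.attributes
        if not measures:
            raise ConfigurationError("data mode JAR requires at least one attribute")
    else:
        measures = table.measures
    consumers = table.consumers
    labels = [(p, m) for p in table.products for m in sorted(measures)]
    wide = table.frame.pivot(index="consumer_id", columns=["product_id", "measure"], values="value")
    cols = pd.MultiIndex.from_tuples(labels, names=["product_id", "measure"])
    matrix = wide.loc[consumers, cols].to_numpy(dtype=float)
    return ConsumerVectors(tuple(consumers), matrix, data_mode, tuple(labels))


# -- CSV I/O ---------------------------------------------------------------

def read_evaluations(
    path,
    scales: dict[str, ScaleSpec] | None = None,
    jar_coded_1_to_5: bool = False,
) -> EvaluationTable:
    """Read a long- or wide-format evaluation CSV (dialect auto-detected).

    Long format has columns consumer_id, [segment,] product_id, measure,
    value; wide format has one ``product|measure`` column per evaluation.
    With ``jar_coded_1_to_5`` JAR attributes stored on a 1..5 scale are
    recentered to the signed -2..+2 coding by subtracting 3.
    """
    df = pd.read_csv(path)
    if "measure" in df.columns and "value" in df.columns:
        long = df
    else:
        pair_cols = [c for c in df.columns if "|" in c]
        if not pair_cols or "consumer_id" not in df.columns:
            raise ConfigurationError(
                f"{path}: neither long (consumer_id/product_id/measure/value) "
                "nor wide (product|measure headers) dialect recognized"
            )
        id_vars = [c for c in ("consumer_id", "segment") if c in df.columns]
        long = df.melt(id_vars=id_vars, value_vars=pair_cols, var_name="_pm", value_name="value")
        long[["product_id", "measure"]] = long["_pm"].str.split("|", n=1, expand=True)
        long = long.drop(columns="_pm")
    if jar_coded_1_to_5:
        long = long.copy()
        jar_rows = long["measure"] != OVERALL_LIKING
        long.loc[jar_rows, "value"] = pd.to_numeric(long.loc[jar_rows, "value"]) - 3
    return EvaluationTable(long, scales=scales)


def write_evaluations(table: EvaluationTable, path, dialect: str = "long") -> None:
    """Write a table to CSV; round-trips through :func:`read_evaluations`."""
    if dialect == "long":
        table.frame.to_csv(path, index=False)
    elif dialect == "wide":
        wide = table.frame.pivot(
            index="consumer_id", columns=["product_id", "measure"], values="value"
        )
        wide.columns = [f"{p}|{m}" for p, m in wide.columns]
        segs = table.segments
        wide.insert(0, "segment", [segs[c] for c in wide.index])
        wide.reset_index().to_csv(path, index=False)
    else:
        raise ConfigurationError(f"unknown CSV dialect {dialect!r}")
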