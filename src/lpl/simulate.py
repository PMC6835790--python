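"""Synthetic consumer panels: segment mean profiles plus Gaussian noise.

The built-in two-segment wine panel emulates a designed tasting study:
50 "women" and 50 "men" consumers, five wines, overall liking on the
9-point hedonic scale plus five JAR attributes (sweetness, acidity,
astringency, body, fruitiness).  Each simulated rating is the segment's
profile mean for that (product, measure) cell plus independent Gaussian
noise, optionally clipped to the scale bounds and optionally rounded to
the nearest scale category.

The default noise standard deviation is 0.5 scale units: small enough
that the two designed segments stay separable (their profile gaps are
1-5 units), large enough to give visible within-segment spread.
Clipping is on by default so every simulated table is a valid panel;
rounding is off so landscapes stay smooth (turn it on for
discreteness-realism studies).  One RNG stream is seeded per call and
drawn consumer-major, then product, then measure (lexicographic), so a
seed pins the exact table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .data import ConfigurationError, EvaluationTable, scale_for_measure

DEFAULT_NOISE_SD = 0.5


@dataclass(frozen=True)
class SegmentProfile:
    """Mean rating profile of one consumer segment."""

    segment_name: str
    n_consumers: int
    means: dict[tuple[str, str], float]  # (product, measure) -> mean

    def __post_init__(self) -> None:
        if self.n_consumers < 1:
            raise ConfigurationError("segment needs at least one consumer")
        for (product, measure), mean in self.means.items():
            spec = scale_for_measure(measure)
            if not spec.contains(mean):
                raise ConfigurationError(
                    f"profile mean {mean} for ({product}, {measure}) outside "
                    f"{spec.name} scale"
                )


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one simulated panel draw."""

    profiles: tuple[SegmentProfile, ...]
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    clip: bool = True
    round_to_scale: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be finite and >= 0")
        if sum(p.n_consumers for p in self.profiles) < 2:
            raise ConfigurationError("need at least 2 consumers in total")
        cells = {frozenset(p.means) for p in self.profiles}
        if len(cells) > 1:
            raise ConfigurationError("all profiles must cover the same cells")


def experiment1_profiles() -> tuple[SegmentProfile, SegmentProfile]:
    """The packaged two-segment wine-panel profiles (50 + 50 consumers)."""
    src = resources.files("lpl._resources").joinpath("experiment1_profiles.csv")
    with src.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    profiles = []
    for name in ("women", "men"):
        sub = df[df["segment"] == name]
        means = {
            (r.product_id, r.measure): float(r.value) for r in sub.itertuples()
        }
        profiles.append(SegmentProfile(name, 50, means))
    return tuple(profiles)


def experiment1_spec(noise_sd: float = DEFAULT_NOISE_SD, seed: int = 0, **kwargs) -> SimulationSpec:
    """Simulation spec for the two-segment wine panel."""
    return SimulationSpec(experiment1_profiles(), noise_sd=noise_sd, seed=seed, **kwargs)


def simulate(spec: SimulationSpec) -> EvaluationTable:
    """Draw one panel from a simulation spec.

    value = profile mean + N(0, noise_sd^2), then clipped to the scale
    bounds if ``spec.clip``, then rounded to the nearest scale category
    if ``spec.round_to_scale``.  Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for profile in spec.profiles:
        products = sorted({p for p, _ in profile.means})
        measures = sorted({m for _, m in profile.means})
        width = len(str(profile.n_consumers))
        for i in range(1, profile.n_consumers + 1):
            consumer = f"{profile.segment_name}_{i:0{width}d}"
            for product in products:
                for measure in measures:
                    mean = profile.means[(product, measure)]
                    value = mean + rng.normal(0.0, spec.noise_sd)
                    spec_scale = scale_for_measure(measure)
                    if spec.clip:
                        value = float(np.clip(value, spec_scale.min_value, spec_scale.max_value))
                    if spec.round_to_scale:
                        value = float(np.clip(round(value), spec_scale.min_value, spec_scale.max_value))
                    records.append(
                        (consumer, profile.segment_name, product, measure, value)
                    )
    df = pd.DataFrame(
        records, columns=["consumer_id", "segment", "product_id", "measure", "value"]
    )
    return EvaluationTable(df)


def simulate_experiment1(
    noise_sd: float = DEFAULT_NOISE_SD, seed: int = 0, **kwargs
) -> EvaluationTable:
    """Convenience: one draw of the built-in two-segment wine panel."""
    return simulate(experiment1_spec(noise_sd=noise_sd, seed=seed, **kwargs))
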