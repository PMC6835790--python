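import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lpl import EvaluationTable, simulate_experiment1

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _close_figures():
    yield
    plt.close("all")


@pytest.fixture(scope="session")
def exp1():
    """One noisy draw of the two-segment wine panel (sd 0.5)."""
    return simulate_experiment1(noise_sd=0.5, seed=7)


@pytest.fixture(scope="session")
def exp1_clean():
    """Noise-free panel: every consumer carries the segment profile."""
    return simulate_experiment1(noise_sd=0.0, seed=0)


def make_table(values, segments=None):
    """Build an EvaluationTable from {(consumer, product, measure): value}."""
    rows = [
        {
            "consumer_id": c,
            "segment": (segments or {}).get(c),
            "product_id": p,
            "measure": m,
            "value": v,
        }
        for (c, p, m), v in values.items()
    ]
    return EvaluationTable(pd.DataFrame(rows))


@pytest.fixture
def tiny_table():
    """2 consumers x 2 products x OL + 1 attribute."""
    vals = {}
    for ci, c in enumerate(["a", "b"]):
        for pi, p in enumerate(["p1", "p2"]):
            vals[(c, p, "overall_liking")] = 3 + 2 * ci + pi
            vals[(c, p, "sweetness")] = ci - pi
    return make_table(vals)
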