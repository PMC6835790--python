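"""Landscape composition: color keys, JAR bars, annotations, shared maps."""

import numpy as np
import pytest

from lpl import (
    ConfigurationError,
    simulate_experiment1,
)
from lpl.viz import (
    HEDONIC_CMAP,
    HEDONIC_NORM,
    JAR_CMAP,
    JAR_NORM,
    CompositionError,
    attribute_analysis,
    compose_lpl,
    jar_bar,
    overall_liking_analysis,
    product_analysis,
)
from .conftest import make_table


@pytest.fixture(scope="module")
def panel():
    return simulate_experiment1(noise_sd=0.5, seed=7)


class TestColorKeys:
    def test_jar_zero_is_green(self):
        r, g, b, _ = JAR_CMAP(JAR_NORM(0.0))
        assert g > 0.5 and g > r and g > b

    def test_hedonic_extremes_blue_vs_red(self):
        r_lo, g_lo, b_lo, _ = HEDONIC_CMAP(HEDONIC_NORM(1.0))
        r_hi, g_hi, b_hi, _ = HEDONIC_CMAP(HEDONIC_NORM(9.0))
        assert b_lo > r_lo  # dislike end is blue
        assert r_hi > b_hi  # like end is red

    def test_jar_anchor_ordering(self):
        # -2 dark blue, +2 red
        lo = JAR_CMAP(JAR_NORM(-2.0))
        hi = JAR_CMAP(JAR_NORM(2.0))
        assert lo[2] > lo[0] and hi[0] > hi[2]


class TestJarBar:
    def test_all_just_about_right(self):
        vals = {(c, "p1", m): (5 if m == "overall_liking" else 0) for c in "abcd" for m in ["overall_liking", "sweetness"]}
        props = jar_bar(make_table(vals), "p1", "sweetness")
        np.testing.assert_allclose(props, [0, 0, 1, 0, 0])

    def test_even_split_between_extremes(self):
        vals = {}
        for i, c in enumerate("abcd"):
            vals[(c, "p1", "overall_liking")] = 5
            vals[(c, "p1", "sweetness")] = -2 if i < 2 else 2
        props = jar_bar(make_table(vals), "p1", "sweetness")
        np.testing.assert_allclose(props, [0.5, 0, 0, 0, 0.5])

    def test_noise_free_women_wine1_sweetness_all_far_too_little(self):
        t = simulate_experiment1(noise_sd=0.0, seed=0)
        women = [c for c, s in t.segments.items() if s == "women"]
        sub = t.frame[
            t.frame["consumer_id"].isin(women)
            & (t.frame["product_id"] == "wine1")
            & (t.frame["measure"] == "sweetness")
        ]
        assert (sub["value"] == -2).all()

    def test_overall_liking_is_not_a_jar_measure(self, panel):
        with pytest.raises(ConfigurationError):
            jar_bar(panel, "wine1", "overall_liking")

    def test_proportions_sum_to_one(self, panel):
        props = jar_bar(panel, "wine3", "sweetness")
        assert props.sum() == pytest.approx(1.0)


class TestAnalyses:
    def test_overall_analysis_one_figure_per_product(self, panel):
        figs = overall_liking_analysis(panel, seed=0)
        assert sorted(figs) == panel.products
        for fig in figs.values():
            assert fig.color_key == "hedonic"

    def test_annotations_recompute_from_table(self, panel):
        figs = overall_liking_analysis(panel, seed=0)
        for product, fig in figs.items():
            expected = panel.mean(product, "overall_liking")
            assert abs(fig.annotations["mean_grade"] - expected) < 1e-9

    def test_wine4_preferred_by_both_wine1_polarized(self, panel):
        """wine4's landscape is liked by both segments, men more; wine1's
        splits the map into a liking and a disliking cluster."""
        figs = overall_liking_analysis(panel, seed=0)
        segs = panel.segments
        emb = figs["wine4"].embedding
        men = np.array([segs[c] == "men" for c in emb.consumer_ids])

        def seg_means(fig, product):
            g = panel.values_for(product, "overall_liking").to_numpy()
            return g[men].mean(), g[~men].mean()

        m4, w4 = seg_means(figs["wine4"], "wine4")
        assert m4 > 5 and w4 > 5 and m4 > w4
        m1, w1 = seg_means(figs["wine1"], "wine1")
        assert m1 > 5 and w1 < 5

    def test_product_analysis_shares_consumer_positions(self, panel):
        figs = product_analysis(panel, "wine3", seed=0)
        assert sorted(figs) == sorted(["overall_liking"] + panel.attributes)
        coords = [fig.embedding.coords for fig in figs.values()]
        for c in coords[1:]:
            np.testing.assert_array_equal(coords[0], c)

    def test_attribute_analysis_jar_percent_matches_bar(self, panel):
        figs = attribute_analysis(panel, "sweetness", seed=0)
        assert sorted(figs) == panel.products
        for product, fig in figs.items():
            props = jar_bar(panel, product, "sweetness")
            assert fig.annotations["jar_percent"] == pytest.approx(props[2] * 100)

    def test_single_product_single_figure(self):
        vals = {}
        for i, c in enumerate("abcdef"):
            vals[(c, "p1", "overall_liking")] = 2 + i
            vals[(c, "p1", "sweetness")] = i % 3 - 1
            vals[(c, "p2", "overall_liking")] = 8 - i
            vals[(c, "p2", "sweetness")] = -(i % 3 - 1)
            vals[(c, "p3", "overall_liking")] = 5 + (i % 2)
            vals[(c, "p3", "sweetness")] = 0
        t = make_table(vals)
        figs = attribute_analysis(t, "sweetness", seed=0)
        assert len(figs) == 3

    def test_grid_mismatch_rejected(self, panel):
        figs = overall_liking_analysis(panel, seed=0)
        fig = figs["wine1"]
        from lpl import estimate_density, GridSpec

        other = estimate_density(fig.embedding, grid=GridSpec(-1, 1, -1, 1, 10))
        with pytest.raises(CompositionError):
            compose_lpl(fig.surface, other, panel, fig.embedding)

    def test_svg_export_deterministic(self, panel, tmp_path):
        for name in ("a", "b"):
            figs = overall_liking_analysis(panel, seed=0)
            figs["wine1"].save(tmp_path / f"{name}.svg")
        assert (tmp_path / "a.svg").read_bytes() == (tmp_path / "b.svg").read_bytes()

    def test_alpha_normalization_endpoints(self, panel):
        """Opacity is density over its own max: densest node fully opaque,
        empty regions fully transparent (white)."""
        figs = overall_liking_analysis(panel, seed=0)
        fig = figs["wine1"]
        alpha = fig.density.values / fig.density.values.max()
        assert alpha.max() == pytest.approx(1.0)
        assert alpha.min() >= 0.0
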