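"""Consumer maps: PCA scores, the IPM variant, SMACOF MDS and their oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from sklearn.manifold import smacof

from lpl import (
    DegenerateInputError,
    MDSEmbedding,
    RankError,
    embed_ipm,
    embed_mds,
    embed_pca,
    kruskal_stress,
    segment_separation,
    to_vectors,
)
from lpl.embed import _classical_scaling
from .conftest import make_table

rng = np.random.default_rng(42)


def planar_cloud(n=30, d=8, seed=0):
    """Points lying exactly in a 2-D plane embedded in R^d."""
    r = np.random.default_rng(seed)
    basis = np.linalg.qr(r.normal(size=(d, 2)))[0]
    z = r.normal(size=(n, 2)) * [3.0, 1.0]
    return z @ basis.T + r.normal(size=d)


class FakeVectors:
    def __init__(self, matrix):
        self.matrix = np.asarray(matrix, float)
        self.consumer_ids = tuple(f"c{i}" for i in range(len(matrix)))
        self.data_mode = "OLJAR"
        self.column_labels = tuple(("p", f"m{j}") for j in range(matrix.shape[1]))


class TestPCA:
    def test_planar_data_embeds_losslessly(self):
        X = planar_cloud()
        emb = embed_pca(FakeVectors(X))
        np.testing.assert_allclose(pdist(emb.coords), pdist(X), atol=1e-8)
        assert emb.explained_variance[0] >= emb.explained_variance[1]
        assert abs(sum(emb.explained_variance) - 1.0) < 1e-8

    def test_duplicate_rows_get_identical_coordinates(self):
        X = np.vstack([planar_cloud(10), planar_cloud(10)])
        emb = embed_pca(FakeVectors(X))
        np.testing.assert_array_equal(emb.coords[:10], emb.coords[10:])

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            embed_pca(FakeVectors(np.ones((5, 4))))

    def test_rank2_optimality_vs_random_projections(self):
        """Eckart-Young: PCA's 2-D reconstruction beats random rank-2
        projections."""
        X = rng.normal(size=(40, 6)) @ np.diag([3, 2, 1, 0.5, 0.3, 0.1])
        Xc = X - X.mean(axis=0)
        emb = embed_pca(FakeVectors(X))
        pca_energy = (emb.coords**2).sum()
        for s in range(10):
            Q = np.linalg.qr(np.random.default_rng(s).normal(size=(6, 2)))[0]
            rand_energy = ((Xc @ Q) ** 2).sum()
            assert pca_energy >= rand_energy - 1e-9

    def test_deterministic_across_calls(self):
        X = planar_cloud(seed=3)
        a = embed_pca(FakeVectors(X)).coords
        b = embed_pca(FakeVectors(X)).coords
        np.testing.assert_array_equal(a, b)


class TestIPM:
    def _ol_table(self, grades):
        """grades: consumers x products array of hedonic values."""
        vals = {}
        for i, row in enumerate(grades):
            for j, g in enumerate(row):
                vals[(f"c{i}", f"p{j}", "overall_liking")] = g
        return make_table(vals)

    def test_identical_consumers_coincide(self):
        t = self._ol_table(np.tile([2, 5, 8], (4, 1)))
        emb = embed_ipm(t)
        assert np.allclose(emb.coords - emb.coords[0], 0.0, atol=1e-9)

    def test_toy_matrix_matches_eigendecomposition_oracle(self):
        grades = np.array(
            [[2.0, 5.0, 8.0], [3.0, 4.0, 9.0], [7.0, 6.0, 1.0], [5.0, 5.0, 6.0]]
        )
        t = self._ol_table(grades)
        emb = embed_ipm(t)
        # independent oracle: eigendecomposition of the 3x3 Gram matrix of
        # the consumer-centered products-by-consumers matrix
        M = grades.T  # P x n
        Mc = M - M.mean(axis=0)
        G = Mc @ Mc.T
        w, U = np.linalg.eigh(G)
        order = np.argsort(w)[::-1][:2]
        w, U = w[order], U[:, order]
        scores = U * np.sqrt(w)
        loadings = Mc.T @ U / np.sqrt(w)
        for k in range(2):  # canonical sign: largest-|loading| positive
            j = np.argmax(np.abs(loadings[:, k]))
            if loadings[j, k] < 0:
                loadings[:, k] *= -1
                scores[:, k] *= -1
        expected = loadings * scores.var(axis=0, ddof=1)
        np.testing.assert_allclose(emb.coords, expected, atol=1e-8)
        np.testing.assert_allclose(emb.product_coords, scores, atol=1e-8)

    def test_fewer_than_three_products_rejected(self):
        t = self._ol_table(np.array([[1.0, 9.0], [9.0, 1.0], [5.0, 5.0]]))
        with pytest.raises(RankError):
            embed_ipm(t)

    def test_consumer_vector_length_grows_with_grade_variance(self):
        grades = np.array(
            [[1.0, 5.0, 9.0],  # strong preference pattern
             [4.5, 5.0, 5.5],  # nearly flat grader
             [2.0, 6.0, 8.0],
             [3.0, 5.0, 8.0]]
        )
        emb = embed_ipm(self._ol_table(grades))
        norms = np.linalg.norm(emb.coords, axis=1)
        assert norms[0] > norms[1]


class TestMDS:
    def test_intrinsically_2d_input_has_zero_stress(self):
        X = planar_cloud(n=25, d=10, seed=1)
        emb = embed_mds(FakeVectors(X), seed=0)
        assert emb.stress <= 1e-6
        np.testing.assert_allclose(pdist(emb.coords), pdist(X), rtol=1e-4)

    def test_stress_monotone_over_iterations(self):
        X = rng.normal(size=(30, 7))
        est = MDSEmbedding(seed=0).fit(X)
        assert np.all(np.diff(est.stress_history_) <= 1e-9)

    def test_beats_classical_scaling_oracle(self):
        """SMACOF refinement cannot be worse than its Torgerson start."""
        r = np.random.default_rng(4)
        X = r.normal(size=(4, 10))
        D = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        D[iu] = pdist(X)
        D += D.T
        est = MDSEmbedding(seed=0).fit(X)
        oracle = kruskal_stress(D, _classical_scaling(D, 2))
        assert est.stress_ <= oracle + 1e-12

    def test_comparable_to_sklearn_smacof(self):
        X = rng.normal(size=(40, 12))
        est = MDSEmbedding(seed=0).fit(X)
        D = np.zeros((40, 40))
        iu = np.triu_indices(40, 1)
        D[iu] = pdist(X)
        D += D.T
        coords, _ = smacof(D, n_components=2, n_init=4, random_state=0, normalized_stress=False)
        assert est.stress_ <= kruskal_stress(D, coords) * 1.02

    def test_identical_vectors_rejected(self):
        with pytest.raises(DegenerateInputError):
            embed_mds(FakeVectors(np.ones((6, 3))), seed=0)

    def test_fixed_seed_reproducible(self):
        X = rng.normal(size=(20, 5))
        a = embed_mds(FakeVectors(X), seed=3).coords
        b = embed_mds(FakeVectors(X), seed=3).coords
        np.testing.assert_array_equal(a, b)


class TestSegmentStructure:
    def test_oljar_maps_separate_the_designed_segments(self, exp1):
        segs = exp1.segments
        v = to_vectors(exp1, "OLJAR")
        for emb in (embed_pca(v), embed_mds(v, seed=0)):
            assert segment_separation(emb, segs) > 1.0

    def test_all_techniques_separate_designed_segments(self):
        """Median over 20 draws: every map technique places the two
        designed segments in disjoint clouds (centroid gap exceeding the
        larger within-segment spread).  The designed overall-liking
        profiles alone already carry strong segment signal, so the
        OL-only IPM variant separates as cleanly as the full-information
        maps under this generator."""
        from lpl import simulate_experiment1

        ratios_pca, ratios_mds, ratios_ipm = [], [], []
        for seed in range(20):
            t = simulate_experiment1(noise_sd=0.5, seed=seed)
            segs = t.segments
            v = to_vectors(t, "OLJAR")
            ratios_pca.append(segment_separation(embed_pca(v), segs))
            ratios_mds.append(segment_separation(embed_mds(v, seed=seed), segs))
            ratios_ipm.append(segment_separation(embed_ipm(t), segs))
        assert np.median(ratios_pca) > 1.0
        assert np.median(ratios_mds) > 1.0
        assert np.median(ratios_ipm) > 1.0

    def test_embedding_invariant_to_consumer_order(self, exp1):
        from lpl import EvaluationTable

        v1 = to_vectors(exp1, "OLJAR")
        shuffled = EvaluationTable(exp1.frame.sample(frac=1.0, random_state=9))
        v2 = to_vectors(shuffled, "OLJAR")
        np.testing.assert_array_equal(embed_pca(v1).coords, embed_pca(v2).coords)
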