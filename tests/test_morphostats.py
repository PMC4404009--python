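"""Randomisation statistics: polygonality, triangle similarity, enrichment."""

import numpy as np
import pytest

from ammopareto import (
    Polytope,
    enrichment_by_distance,
    polygonality_test,
    sample_polytope,
    similarity_test,
    t_ratio,
    triangle_similarity,
)
from conftest import TRIANGLE_DW


def tri(*pts):
    return Polytope(np.array(pts, dtype=float), kind="simplex")


class TestTRatio:
    def test_perfectly_polygonal_data(self):
        T = tri((0.0, 1.0), (1.0, 1.0), (0.0, 3.0))
        interior = np.array([[0.3, 1.5], [0.1, 1.2], [0.4, 1.9]])
        pts = np.vstack([T.vertices, interior])
        assert t_ratio(pts, T) == pytest.approx(1.0)

    def test_square_in_double_triangle_is_half(self):
        square = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        T = tri((0.0, 0.0), (2.0, 0.0), (0.0, 2.0))
        assert t_ratio(square, T) == pytest.approx(0.5)

    def test_collinear_data_gives_zero(self):
        pts = np.column_stack([np.linspace(0, 1, 20), np.linspace(0, 1, 20)])
        assert t_ratio(pts, tri((0.0, 0.0), (2.0, 0.0), (0.0, 2.0))) == 0.0

    def test_zero_area_simplex_rejected(self):
        with pytest.raises(ValueError):
            t_ratio(np.random.default_rng(0).random((10, 2)),
                    tri((0.0, 0.0), (1.0, 1.0), (2.0, 2.0)))


class TestPolygonality:
    def test_triangular_data_is_significant(self):
        pts, _ = sample_polytope(TRIANGLE_DW, 200, 0.8, noise_sd=0.01, seed=2)
        res = polygonality_test(pts, n_null=150, seed=0,
                                fit_kwargs=dict(maxiter=600))
        assert res.p_value < 0.05
        assert 0 < res.statistic <= 1.001

    def test_gaussian_blob_is_not_significant(self):
        blob = np.random.default_rng(8).standard_normal((150, 2))
        res = polygonality_test(blob, n_null=120, seed=0,
                                fit_kwargs=dict(maxiter=600))
        assert res.p_value > 0.1

    def test_pvalues_roughly_uniform_under_null(self):
        # with independent columns, permuted replicates are exchangeable
        # with the data even under a fixed fitted triangle (the common
        # denominator cancels), so the cheap no-refit variant is calibrated
        # here and p-values should not pile up near zero
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(30):
            data = np.column_stack([rng.random(80), rng.random(80) * 2 + 1])
            ps.append(
                polygonality_test(data, n_null=150,
                                  seed=int(rng.integers(2**31 - 1)),
                                  refit_null=False).p_value
            )
        ps = np.array(ps)
        assert (ps < 0.05).mean() <= 0.2
        assert 0.2 <= (ps < 0.5).mean() <= 0.8

    def test_invalid_configuration_rejected(self):
        pts = np.random.default_rng(0).random((50, 2))
        with pytest.raises(ValueError):
            polygonality_test(pts, n_null=0)
        with pytest.raises(ValueError):
            polygonality_test(pts[:5], n_null=10)


class TestTriangleSimilarity:
    A = tri((0.0, 0.0), (1.0, 0.0), (0.0, 1.0))

    def test_identical_triangles(self):
        assert triangle_similarity(self.A, self.A) == pytest.approx(1.0)

    def test_disjoint_triangles(self):
        B = tri((5.0, 5.0), (6.0, 5.0), (5.0, 6.0))
        assert triangle_similarity(self.A, B) == 0.0

    def test_symmetric_and_scale_invariant(self):
        B = tri((0.5, 0.0), (1.5, 0.0), (0.5, 1.0))
        r1 = triangle_similarity(self.A, B)
        assert r1 == pytest.approx(triangle_similarity(B, self.A))
        scale = np.array([3.0, 0.5])
        A2 = Polytope(self.A.vertices * scale, kind="simplex")
        B2 = Polytope(B.vertices * scale, kind="simplex")
        assert triangle_similarity(A2, B2) == pytest.approx(r1, rel=1e-12)

    def test_matches_monte_carlo_rejection_oracle(self):
        B = tri((0.5, 0.0), (1.5, 0.0), (0.5, 1.0))
        exact = triangle_similarity(self.A, B)
        rng = np.random.default_rng(0)
        pts = rng.random((2_000_000, 2)) * [1.5, 1.0]

        def in_tri(P, V):
            T = np.column_stack([V[1] - V[0], V[2] - V[0]])
            lam = np.linalg.solve(T, (P - V[0]).T).T
            return (lam[:, 0] >= 0) & (lam[:, 1] >= 0) & (lam.sum(1) <= 1)

        ia, ib = in_tri(pts, self.A.vertices), in_tri(pts, B.vertices)
        mc = (ia & ib).mean() / (ia | ib).mean()
        assert exact == pytest.approx(mc, abs=3e-3)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            triangle_similarity(self.A, tri((0, 0), (1, 1), (2, 2)))


class TestSimilarityTest:
    def test_zero_ratio_has_p_one(self):
        res = similarity_test(0.0, n_null=500, seed=0)
        assert res.p_value == 1.0

    def test_p_floor_never_zero(self):
        res = similarity_test(0.999, n_null=500, seed=0)
        assert res.p_value == pytest.approx(1 / 500)

    def test_rectangle_invariance_of_the_ratio(self):
        # the IoU of a triangle pair is invariant under any axis scaling
        # applied to both triangles, so the null is rectangle independent
        from shapely.geometry import Polygon

        rng = np.random.default_rng(3)
        for _ in range(100):
            v = rng.random((2, 3, 2))
            r_unit = (Polygon(v[0]).intersection(Polygon(v[1])).area
                      / Polygon(v[0]).union(Polygon(v[1])).area)
            w = v * np.array([3.0, 1.0])
            r_rect = (Polygon(w[0]).intersection(Polygon(w[1])).area
                      / Polygon(w[0]).union(Polygon(w[1])).area)
            assert r_rect == pytest.approx(r_unit, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            similarity_test(1.2)
        with pytest.raises(ValueError):
            similarity_test(0.5, n_null=0)


class TestEnrichment:
    def make_planted(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.random((n, 3)) * [0.7, 3.0, 3.5] + [0, 0.2, 1.0]
        vertex = np.array([0.05, 0.3, 4.0])
        sd = X.std(axis=0)
        dist = np.linalg.norm((X - vertex) / sd, axis=1)
        values = 5.0 * np.exp(0.4 * dist) * np.exp(0.2 * rng.standard_normal(n))
        return X, values, vertex

    def test_planted_positive_trend_detected(self):
        X, values, vertex = self.make_planted()
        res = enrichment_by_distance(X, values, vertex, n_perm=500, seed=0)
        assert res.direction == "positive"
        assert res.slope > 0
        assert res.p_value < 0.05

    def test_shuffled_values_show_no_trend(self):
        X, values, vertex = self.make_planted(seed=1)
        shuffled = np.random.default_rng(10).permutation(values)
        res = enrichment_by_distance(X, shuffled, vertex, n_perm=500, seed=0)
        assert res.p_value > 0.05

    def test_equal_count_bins(self):
        X, values, vertex = self.make_planted(n=97)
        res = enrichment_by_distance(X, values, vertex, n_bins=10, n_perm=50, seed=0)
        assert len(res.bin_means) == 10

    def test_constant_values_give_null_result(self):
        X, _, vertex = self.make_planted(n=50)
        res = enrichment_by_distance(X, np.full(50, 2.0), vertex, n_perm=100, seed=0)
        assert res.slope == 0.0 and res.p_value == 1.0 and res.direction == "none"

    def test_invalid_inputs_rejected(self):
        X, values, vertex = self.make_planted(n=20)
        with pytest.raises(ValueError):
            enrichment_by_distance(X, values, vertex, n_bins=30)
        with pytest.raises(ValueError):
            enrichment_by_distance(X, -values, vertex)
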