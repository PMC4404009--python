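"""Polytope fitting: minimum-volume triangles, PCHA pyramids, projections."""

import numpy as np
import pytest

from ammopareto import (
    PYRAMID_VERTICES,
    Polytope,
    fit_pcha,
    fit_simplex,
    project,
    rms_profile,
    sample_polytope,
)
from conftest import TRIANGLE_DW, match_vertices

PYRAMID_SPAN = np.ptp(PYRAMID_VERTICES, axis=0)
TRIANGLE_SPAN = np.ptp(TRIANGLE_DW, axis=0)


class TestPolytope:
    def test_simplex_needs_d_plus_one_vertices(self):
        with pytest.raises(ValueError):
            Polytope(np.zeros((4, 2)), kind="simplex")

    def test_area_and_membership(self):
        tri = Polytope(np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0]]), kind="simplex")
        assert tri.volume() == pytest.approx(2.0)
        inside = tri.contains(np.array([[0.5, 0.5], [1.9, 1.9]]), tol=1e-6)
        assert inside.tolist() == [True, False]


class TestFitSimplex:
    def test_exact_polytope_data_recovered(self):
        pts, _ = sample_polytope(TRIANGLE_DW, 300, concentration=0.5,
                                 noise_sd=0.0, seed=1)
        fit = fit_simplex(pts, seed=0)
        err = match_vertices(fit.polytope.vertices, TRIANGLE_DW) / TRIANGLE_SPAN
        # soft-enclosure equilibrium leaves a small outward offset
        assert err.max() < 0.04
        assert fit.rms_error == pytest.approx(0.0, abs=1e-12)
        assert fit.fraction_inside == 1.0

    def test_noisy_recovery_within_range_fraction(self, triangle_data):
        pts, _ = triangle_data
        fit = fit_simplex(pts, seed=0)
        err = match_vertices(fit.polytope.vertices, TRIANGLE_DW) / TRIANGLE_SPAN
        assert err.max() < 0.15
        assert fit.fraction_inside >= 0.95

    def test_recovery_improves_as_noise_vanishes(self):
        errs = []
        for noise in (0.02, 0.005):
            pts, _ = sample_polytope(TRIANGLE_DW, 500, 0.3, noise_sd=noise, seed=9)
            fit = fit_simplex(pts, seed=0)
            errs.append(
                (match_vertices(fit.polytope.vertices, TRIANGLE_DW) / TRIANGLE_SPAN).max()
            )
        assert errs[1] < errs[0]

    def test_degenerate_data_rejected(self):
        line = np.column_stack([np.linspace(0, 1, 50), np.linspace(0, 2, 50)])
        with pytest.raises(ValueError):
            fit_simplex(line, seed=0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_simplex(np.random.default_rng(0).random((3, 2)), seed=0)


class TestFitPCHA:
    def test_repeated_distinct_points_are_archetypes(self):
        base = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.5], [0.0, 1.0, 1.0],
                         [1.0, 1.0, 0.2], [0.5, 0.2, 2.0]])
        pts = np.repeat(base, 40, axis=0)
        rep = fit_pcha(pts, k=5, restarts=4, seed=0)
        assert rep.rms_error < 1e-3
        err = match_vertices(rep.polytope.vertices, base)
        assert err.max() < 0.02

    def test_pyramid_vertex_recovery(self, pyramid_data):
        pts, _ = pyramid_data
        rep = fit_pcha(pts, k=5, restarts=6, seed=0)
        err = match_vertices(rep.polytope.vertices, PYRAMID_VERTICES) / PYRAMID_SPAN
        assert err.max() <= 0.1
        assert rep.converged

    def test_four_base_vertices_roughly_coplanar(self, pyramid_data):
        # the fitted pyramid inherits the near-planar square base of the
        # generating polytope (compared in standardised coordinates)
        pts, _ = pyramid_data
        sd = pts.std(axis=0)

        def base_planarity(V):
            apex = int(np.argmax(V[:, 2]))      # the high-W growth archetype
            B = np.delete(V, apex, axis=0)
            B = (B - B.mean(axis=0)) / sd
            return float(np.abs(B @ np.linalg.svd(B)[2][-1]).max())

        rep = fit_pcha(pts, k=5, restarts=6, seed=0)
        fitted = base_planarity(rep.polytope.vertices)
        truth = base_planarity(PYRAMID_VERTICES)
        assert fitted <= 1.5 * truth

    def test_rms_invariant_under_rotation(self):
        rng = np.random.default_rng(5)
        pts, _ = sample_polytope(PYRAMID_VERTICES, 300, 0.3, 0.01, seed=2)
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        a = fit_pcha(pts, k=5, restarts=4, seed=0, standardize=False)
        b = fit_pcha(pts @ Q.T + 1.7, k=5, restarts=4, seed=0, standardize=False)
        assert a.rms_error == pytest.approx(b.rms_error, abs=5e-3)

    def test_invalid_k_rejected(self):
        pts = np.random.default_rng(0).random((20, 3))
        with pytest.raises(ValueError):
            fit_pcha(pts, k=1)
        with pytest.raises(ValueError):
            fit_pcha(pts, k=21)
        with pytest.raises(ValueError):
            fit_pcha(pts, k=3, delta=-0.1)


class TestRmsProfile:
    def test_exact_pyramid_elbow_at_five(self):
        pts, _ = sample_polytope(PYRAMID_VERTICES, 400, 0.25, noise_sd=0.0, seed=6)
        prof = rms_profile(pts, k_range=range(2, 8), restarts=3, seed=0)
        ks = sorted(prof)
        assert all(prof[b] <= prof[a] + 1e-6 for a, b in zip(ks, ks[1:]))
        assert prof[5] < 0.02
        assert prof[4] > 10 * prof[5]
        assert prof[6] < 0.02

    def test_segment_data_elbow_at_two(self):
        ends = np.array([[0.0, 0.2, 1.0], [0.6, 2.0, 4.0]])
        pts, _ = sample_polytope(ends, 300, concentration=0.5, noise_sd=0.0, seed=8)
        prof = rms_profile(pts, k_range=range(2, 5), restarts=3, seed=0)
        assert prof[2] < 1e-3
        assert prof[3] <= prof[2] + 1e-6


class TestProject:
    def test_pyramid_projects_to_three_clusters(self):
        pyr = Polytope(PYRAMID_VERTICES, trait_names=("D", "S", "W"))
        proj, merge_map = project(pyr, axes=(0, 2), merge_tol=0.3)   # (D, W) plane
        assert proj.k == 3
        # economy pairs with compact-economy, drag with compact-drag,
        # growth stays alone
        assert merge_map[0] == merge_map[3]
        assert merge_map[1] == merge_map[4]
        assert len({merge_map[2], merge_map[0], merge_map[1]}) == 3

    def test_projection_to_one_axis_spans_vertex_range(self):
        tri = Polytope(np.array([[0.0, 1.0], [0.7, 1.35], [0.0, 4.6]]))
        proj, _ = project(tri, axes=(1,), merge_tol=0.0)
        vals = proj.vertices.ravel()
        assert vals.min() == pytest.approx(1.0)
        assert vals.max() == pytest.approx(4.6)

    def test_projected_vertices_subset_of_vertex_projections(self):
        rng = np.random.default_rng(3)
        V = rng.random((6, 3))
        proj, _ = project(Polytope(V), axes=(0, 1), merge_tol=0.0)
        for v in proj.vertices:
            assert np.min(np.linalg.norm(V[:, :2] - v, axis=1)) < 1e-12

    def test_invalid_axes_rejected(self):
        with pytest.raises(ValueError):
            project(Polytope(np.random.random((4, 3))), axes=(0, 3))
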