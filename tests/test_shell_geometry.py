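"""Raup shell geometry: radii, sections, overlap, volume ratios."""

import numpy as np
import pytest

from ammopareto import (
    ShellModel,
    diameter_factor,
    spiral_radius,
    surface_to_volume,
    volume_ratio,
    volume_ratio_many,
    whorl_overlap,
    whorl_section,
)


def ellipse_polyline_perimeter(a, b, n=200_000):
    """Independent arc-length oracle: dense polyline around the ellipse."""
    phi = np.linspace(0, 2 * np.pi, n)
    x, y = a * np.cos(phi), b * np.sin(phi)
    return float(np.sum(np.hypot(np.diff(x), np.diff(y))))


class TestSpiralBasics:
    @pytest.mark.parametrize(
        "D, W, theta, expected",
        [
            (0.5, 1.0, 1.7, 1.0),              # W=1 degenerates to a circle
            (0.004, 4.59, 2 * np.pi, 4.59),    # one whorl multiplies by W
            (0.2, 2.0, np.pi, np.sqrt(2.0)),   # half whorl = sqrt(W)
        ],
    )
    def test_spiral_radius(self, D, W, theta, expected):
        assert spiral_radius(ShellModel(D=D, W=W), theta) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "W, expected",
        [(1.0, 2.0), (4.0, 1.5), (4.44, 1.4745)],
    )
    def test_diameter_factor(self, W, expected):
        assert diameter_factor(ShellModel(D=0.1, W=W)) == pytest.approx(expected, abs=1e-4)

    def test_diameter_factor_decreasing_to_two(self):
        Ws = np.linspace(1.0, 6.0, 40)
        vals = [diameter_factor(ShellModel(D=0.1, W=w)) for w in Ws]
        assert np.all(np.diff(vals) < 0)
        assert vals[0] == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "D, W, overlaps",
        [(0.7, 1.35, True), (0.5, 2.0, False), (0.003, 4.59, True)],
    )
    def test_whorl_overlap(self, D, W, overlaps):
        flag, depth = whorl_overlap(ShellModel(D=D, W=W))
        assert flag is overlaps
        assert depth == pytest.approx(max(0.0, 1 / W - D))

    @pytest.mark.parametrize(
        "kwargs",
        [dict(D=-0.1, W=2), dict(D=1.0, W=2), dict(D=0.2, W=0.9),
         dict(D=0.2, W=2, S=0.0), dict(D=0.2, W=2, thickness_fraction=0.0)],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ShellModel(**kwargs)


class TestWhorlSection:
    @pytest.mark.parametrize(
        "S, D, area, perim",
        [
            (1.0, 0.0, np.pi / 4, np.pi),      # circle of diameter 1
            (1.0, 0.5, np.pi / 16, np.pi / 2), # circle of diameter 1/2
        ],
    )
    def test_circular_sections(self, S, D, area, perim):
        sec = whorl_section(ShellModel(D=D, W=3.0, S=S))
        # the area integrand has square-root endpoints; 256-node quadrature
        # resolves it to ~1e-7 relative
        assert sec.area == pytest.approx(area, rel=1e-6)
        assert sec.total_perimeter == pytest.approx(perim, rel=1e-9)

    def test_perimeter_matches_polyline_oracle(self):
        shell = ShellModel(D=0.2, W=6.0, S=0.3)   # gyroconic: full perimeter
        sec = whorl_section(shell)
        a = (1 - shell.D) / 2
        oracle = ellipse_polyline_perimeter(a, shell.S * a)
        assert sec.total_perimeter == pytest.approx(oracle, rel=1e-6)
        assert sec.exposed_perimeter == pytest.approx(sec.total_perimeter)

    def test_overlapping_section_shares_wall(self):
        sec = whorl_section(ShellModel(D=0.65, W=1.35, S=0.69))
        assert sec.exposed_perimeter < sec.total_perimeter

    def test_degenerate_aperture_rejected(self):
        with pytest.raises(ValueError):
            whorl_section(ShellModel(D=1 - 1e-12, W=2.0))


class TestVolumeRatio:
    def test_constant_on_gyroconic_region(self):
        # non-overlapping whorls: the ratio depends on S only
        rng = np.random.default_rng(11)
        D = rng.uniform(0.05, 0.9, 25)
        W = 1.0 / D * rng.uniform(1.05, 2.0, 25)    # W > 1/D
        vals = volume_ratio_many(D, 1.0, W)
        assert np.allclose(vals, vals[0], rtol=1e-7)
        # equals the closed-form circle value pi*S/(t * unit perimeter)
        assert vals[0] == pytest.approx(1.0 / (2 * 0.077), rel=1e-6)

    def test_gyroconic_value_matches_polyline_oracle(self):
        # ratio = pi a b c / (t sqrt(ab) * c * perimeter) for ellipse sections
        D, S, W = 0.3, 0.4, 5.0
        a = (1 - D) / 2
        b = S * a
        peri = ellipse_polyline_perimeter(a, b)
        expected = np.pi * a * b / (0.077 * np.sqrt(a * b) * peri)
        assert volume_ratio(ShellModel(D=D, W=W, S=S)) == pytest.approx(
            expected, rel=1e-5
        )

    def test_inverse_proportional_to_thickness(self):
        base = ShellModel(D=0.4, W=1.2, S=0.8)
        thick = base.with_(thickness_fraction=2 * base.thickness_fraction)
        assert volume_ratio(thick) == pytest.approx(volume_ratio(base) / 2, rel=1e-12)

    def test_monotone_decreasing_in_thickness(self):
        ts = [0.04, 0.077, 0.12, 0.2]
        vals = [volume_ratio(ShellModel(D=0.5, W=1.3, thickness_fraction=t)) for t in ts]
        assert np.all(np.diff(vals) < 0)

    def test_overlap_raises_ratio_above_gyroconic(self):
        # shared walls make involute shells cheaper per internal volume
        gyro = volume_ratio(ShellModel(D=0.2, W=8.0))
        involute = volume_ratio(ShellModel(D=0.65, W=1.35))
        assert involute > gyro

    def test_near_zero_not_reached_and_positive(self):
        vals = volume_ratio_many([0.01, 0.04], [1.8, 0.2], [1.07, 1.55])
        assert np.all(vals > 0)

    def test_invalid_D_rejected(self):
        with pytest.raises(ValueError):
            volume_ratio_many([1.2], 1.0, [2.0])

    def test_net_area_mode_smaller_in_overlap(self):
        shell = ShellModel(D=0.5, W=1.2)
        assert volume_ratio(shell, internal_area="net") < volume_ratio(shell)


class TestSurfaceToVolume:
    def test_sphericity_minimised_near_circular_opening(self):
        Ss = np.array([0.2, 0.5, 1.0, 2.0, 3.2])
        vals = [surface_to_volume(ShellModel(D=0.2, W=6.0, S=s)) for s in Ss]
        assert int(np.argmin(vals)) == 2

    def test_depressed_archetype_more_globular_than_compressed(self):
        # high-S depressed shell vs low-S compressed shell
        depressed = surface_to_volume(ShellModel(D=0.5, S=3.2, W=1.6))
        compressed = surface_to_volume(ShellModel(D=0.04, S=0.2, W=1.55))
        assert depressed < compressed

    def test_raw_ratio_positive(self):
        assert surface_to_volume(ShellModel(D=0.3, W=2.0), normalized=False) > 0
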