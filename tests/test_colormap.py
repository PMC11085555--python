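"""The invertible hue/saturation phasor colormap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phasorviz as pv
from phasorviz.colormap import (
    principal_angles,
    saturation_geometry_of,
    phasor_colors,
)

from conftest import OMEGA_80MHZ


def ray_point(cfg, direction_point, distance):
    """Point at the given distance from the center toward direction_point."""
    c = pv.resolve_center(cfg).as_array()
    d = direction_point.as_array() - c
    d /= np.hypot(*d)
    return pv.PhasorPoint(*(c + distance * d))


class TestCenterAndAngles:
    def test_default_center_is_mean_of_points(self):
        cfg = pv.ColorMapConfig((pv.PhasorPoint(0, 0), pv.PhasorPoint(1, 0),
                                 pv.PhasorPoint(0, 1)))
        c = pv.resolve_center(cfg)
        assert (c.g, c.s) == pytest.approx((1 / 3, 1 / 3))

    def test_explicit_center_returned_verbatim(self):
        cfg = pv.ColorMapConfig((pv.PhasorPoint(0.2, 0.2),
                                 pv.PhasorPoint(0.8, 0.2)),
                                center=pv.PhasorPoint(0.5, 0.1))
        assert pv.resolve_center(cfg) == pv.PhasorPoint(0.5, 0.1)

    def test_two_points_center_at_midpoint(self):
        cfg = pv.ColorMapConfig((pv.PhasorPoint(0.2, 0.3),
                                 pv.PhasorPoint(0.6, 0.1)))
        c = pv.resolve_center(cfg)
        assert (c.g, c.s) == pytest.approx((0.4, 0.2))

    @pytest.mark.parametrize("n, anchors", [
        (2, [0.0, 0.5, 1.0]),
        (3, [0.0, 1 / 3, 2 / 3, 1.0]),
        (6, [k / 6 for k in range(6)] + [1.0]),
    ])
    def test_equidistant_hue_anchors(self, n, anchors):
        pts = tuple(
            pv.PhasorPoint(0.5 + 0.3 * math.cos(2 * math.pi * k / n),
                           0.25 + 0.2 * math.sin(2 * math.pi * k / n))
            for k in range(n)
        )
        cfg = pv.ColorMapConfig(pts)
        angles, hues = principal_angles(cfg)
        assert hues == pytest.approx(anchors)
        assert angles[0] == 0.0
        assert np.all(np.diff(angles) > 0)

    def test_point_on_center_rejected(self):
        with pytest.raises(ValueError, match="center"):
            pv.ColorMapConfig((pv.PhasorPoint(0.5, 0.2),
                               pv.PhasorPoint(0.3, 0.1)),
                              center=pv.PhasorPoint(0.5, 0.2))


class TestHue:
    def test_hue_anchors_exact_on_principal_rays(self, triangle_cmap):
        for k, p in enumerate(triangle_cmap.principal_points):
            assert pv.hue_of(p, triangle_cmap) == pytest.approx(k / 3, abs=0)
            # anywhere along the ray, not just at the point itself
            far = ray_point(triangle_cmap, p, 0.9)
            assert pv.hue_of(far, triangle_cmap) == pytest.approx(k / 3,
                                                                  abs=1e-12)

    def test_bisector_hue_is_halfway(self, triangle_cmap):
        c = pv.resolve_center(triangle_cmap).as_array()
        p0, p1 = (p.as_array() for p in triangle_cmap.principal_points[:2])
        a0 = math.atan2(*(p0 - c)[::-1])
        a1 = math.atan2(*(p1 - c)[::-1])
        d = (a1 - a0 + math.pi) % (2 * math.pi) - math.pi
        mid = a0 + d / 2
        p = pv.PhasorPoint(c[0] + 0.1 * math.cos(mid), c[1] + 0.1 * math.sin(mid))
        assert pv.hue_of(p, triangle_cmap) == pytest.approx(1 / 6, abs=1e-12)

    def test_hue_continuous_across_wedge_boundaries(self, triangle_cmap):
        c = pv.resolve_center(triangle_cmap).as_array()
        for p in triangle_cmap.principal_points[1:]:
            d = p.as_array() - c
            ang = math.atan2(d[1], d[0])
            lo = pv.hue_of(pv.PhasorPoint(c[0] + 0.2 * math.cos(ang - 1e-12),
                                          c[1] + 0.2 * math.sin(ang - 1e-12)),
                           triangle_cmap)
            hi = pv.hue_of(pv.PhasorPoint(c[0] + 0.2 * math.cos(ang + 1e-12),
                                          c[1] + 0.2 * math.sin(ang + 1e-12)),
                           triangle_cmap)
            assert abs(hi - lo) < 1e-9

    def test_hue_cyclically_monotone(self, triangle_cmap):
        c = pv.resolve_center(triangle_cmap).as_array()
        p0 = triangle_cmap.principal_points[0].as_array()
        start = math.atan2(*(p0 - c)[::-1])
        # this config's points run anticlockwise about the center
        angs = start + np.linspace(1e-6, 2 * math.pi - 1e-6, 400)
        hues = [pv.hue_of(pv.PhasorPoint(c[0] + 0.2 * math.cos(a),
                                         c[1] + 0.2 * math.sin(a)),
                          triangle_cmap) for a in angs]
        assert np.all(np.diff(hues) > 0)


class TestSaturation:
    def test_zero_at_center(self, triangle_cmap):
        assert pv.saturation_of(pv.resolve_center(triangle_cmap),
                                triangle_cmap) == 0.0

    def test_v2_exact_at_semicircle_crossing(self, triangle_cmap):
        for target in triangle_cmap.principal_points:
            geo = saturation_geometry_of(target, triangle_cmap)
            p = ray_point(triangle_cmap, target, geo.d2)
            assert pv.saturation_of(p, triangle_cmap) == pytest.approx(
                0.95, abs=1e-12)

    def test_v1_effective_equals_v2_when_crossings_coincide(self):
        # polygon passing exactly through the semicircle: d1 == d2 there
        cfg = pv.ColorMapConfig((pv.PhasorPoint(0.5, 0.5),
                                 pv.PhasorPoint(0.1, 0.0),
                                 pv.PhasorPoint(0.9, 0.0)))
        geo = saturation_geometry_of(pv.PhasorPoint(0.5, 0.45), cfg)
        assert geo.d1 == pytest.approx(geo.d2, abs=1e-12)
        assert geo.v1_effective == pytest.approx(cfg.v2)

    def test_v1_uncorrected_limit_for_tiny_polygon(self):
        # polygon crossing a million times closer than the semicircle's
        eps = 3e-7
        c = (0.5, 0.2)
        pts = tuple(
            pv.PhasorPoint(c[0] + eps * math.cos(a), c[1] + eps * math.sin(a))
            for a in (math.pi / 2, math.pi / 2 + 2 * math.pi / 3,
                      math.pi / 2 + 4 * math.pi / 3)
        )
        cfg = pv.ColorMapConfig(pts, center=pv.PhasorPoint(*c))
        geo = saturation_geometry_of(pts[0], cfg)
        assert geo.d1 / geo.d2 < 1e-5
        sat_at_d1 = pv.saturation_of(pts[0], cfg)
        assert sat_at_d1 == pytest.approx(0.85, abs=1e-5)

    def test_known_arc_distance_from_interior_center(self):
        cfg = pv.ColorMapConfig((pv.PhasorPoint(0.45, 0.3),
                                 pv.PhasorPoint(0.55, 0.3)),
                                center=pv.PhasorPoint(0.5, 0.25))
        geo = saturation_geometry_of(pv.PhasorPoint(0.5, 0.45), cfg)
        # straight up from (0.5, 0.25): the arc top (0.5, 0.5) is 0.25 away
        assert geo.d2 == pytest.approx(0.25, abs=1e-12)

    def test_profile_continuous_at_breakpoints(self, triangle_cmap):
        target = triangle_cmap.principal_points[0]
        geo = saturation_geometry_of(target, triangle_cmap)
        v1e, v2 = geo.v1_effective, triangle_cmap.v2
        sin_end = v1e * math.sin(math.pi / 2)
        lin_start = v1e
        lin_end = v1e + (v2 - v1e)
        exp_start = 1 - (1 - v2) * math.exp(0.0)
        assert sin_end == pytest.approx(lin_start, abs=1e-12)
        assert lin_end == pytest.approx(exp_start, abs=1e-12)
        for d, ref in ((geo.d1, v1e), (geo.d2, v2)):
            p = ray_point(triangle_cmap, target, d)
            assert pv.saturation_of(p, triangle_cmap) == pytest.approx(
                ref, abs=1e-12)

    def test_strictly_increasing_with_asymptote_one(self, triangle_cmap):
        target = triangle_cmap.principal_points[1]
        radii = np.linspace(1e-4, 3.0, 300)
        sats = [pv.saturation_of(ray_point(triangle_cmap, target, r),
                                 triangle_cmap) for r in radii]
        assert np.all(np.diff(sats) > 0)
        assert sats[-1] < 1.0
        far = pv.saturation_of(ray_point(triangle_cmap, target, 50.0),
                               triangle_cmap)
        assert far == pytest.approx(1.0, abs=1e-9)

    def test_center_outside_polygon_falls_back_continuously(self):
        # center far from the triangle: rays away from it miss the polygon
        cfg = pv.ColorMapConfig((pv.PhasorPoint(0.7, 0.3),
                                 pv.PhasorPoint(0.8, 0.35),
                                 pv.PhasorPoint(0.75, 0.25)),
                                center=pv.PhasorPoint(0.2, 0.1))
        away = pv.PhasorPoint(0.1, 0.05)  # opposite direction from polygon
        sats = [pv.saturation_of(ray_point(cfg, away, r), cfg)
                for r in np.linspace(1e-4, 2.0, 200)]
        assert np.all(np.diff(sats) > 0)
        assert 0 < sats[0] < sats[-1] < 1


class TestBijectivity:
    def test_round_trip_on_interior_grid(self, triangle_cmap):
        gs = np.linspace(0.01, 0.99, 50)
        ss = np.linspace(0.005, 0.495, 50)
        worst = 0.0
        n_checked = 0
        for g in gs:
            for s in ss:
                if (g - 0.5) ** 2 + s**2 >= 0.25:
                    continue
                p = pv.PhasorPoint(g, s)
                h, sat = pv.color_of(p, triangle_cmap)
                if sat >= 0.999:
                    continue
                q = pv.invert_color(h, sat, triangle_cmap)
                worst = max(worst, abs(q.g - g), abs(q.s - s))
                n_checked += 1
        assert n_checked > 1000
        assert worst < 1e-9

    def test_zero_color_maps_to_center(self, triangle_cmap):
        c = pv.resolve_center(triangle_cmap)
        q = pv.invert_color(0.0, 0.0, triangle_cmap)
        assert (q.g, q.s) == pytest.approx((c.g, c.s))

    def test_principal_point_recovered_from_its_color(self, triangle_cmap):
        p2 = triangle_cmap.principal_points[1]
        h, sat = pv.color_of(p2, triangle_cmap)
        assert h == pytest.approx(1 / 3)
        q = pv.invert_color(h, sat, triangle_cmap)
        assert (q.g, q.s) == pytest.approx((p2.g, p2.s), abs=1e-12)

    def test_saturation_one_has_no_preimage(self, triangle_cmap):
        with pytest.raises(ValueError):
            pv.invert_color(0.2, 1.0, triangle_cmap)

    TRIANGLE = pv.ColorMapConfig((pv.PhasorPoint(0.8, 0.35),
                                  pv.PhasorPoint(0.25, 0.4),
                                  pv.PhasorPoint(0.5, 0.1)))

    @given(h=st.floats(0, 1, exclude_max=True), sat=st.floats(0.01, 0.998))
    @settings(max_examples=60, deadline=None)
    def test_color_of_inverts_invert_color(self, h, sat):
        triangle_cmap = self.TRIANGLE
        p = pv.invert_color(h, sat, triangle_cmap)
        h2, sat2 = pv.color_of(p, triangle_cmap)
        assert sat2 == pytest.approx(sat, abs=1e-9)
        dh = min(abs(h2 - h), 1 - abs(h2 - h))
        assert dh < 1e-9


class TestIntensityTransfer:
    LOG = pv.RenderConfig(scale="log", log_crossover_percent=1.0)

    def test_linear_is_identity(self):
        rc = pv.RenderConfig(scale="linear")
        x = np.linspace(0, 1, 11)
        assert np.array_equal(pv.intensity_transfer(x, rc), x)

    def test_log_endpoints_and_crossover_value(self):
        assert pv.intensity_transfer(0.0, self.LOG) == 0.0
        assert pv.intensity_transfer(1.0, self.LOG) == pytest.approx(1.0)
        got = pv.intensity_transfer(0.01, self.LOG)
        assert got == pytest.approx(1.0 / (1.0 + math.log(100.0)), abs=1e-12)

    def test_log_continuous_and_monotone(self):
        x = np.linspace(0, 1, 5001)
        v = pv.intensity_transfer(x, self.LOG)
        assert np.all(np.diff(v) > 0)
        assert np.max(np.abs(np.diff(v))) < 1e-2  # no jumps

    def test_out_of_range_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clip"):
            v = pv.intensity_transfer(np.array([-0.5, 1.5]), self.LOG)
        assert v[0] == 0.0 and v[1] == pytest.approx(1.0)

    def test_invalid_crossover_rejected(self):
        with pytest.raises(ValueError):
            pv.RenderConfig(scale="log", log_crossover_percent=0.0)


class TestRenderImage:
    def uniform_field(self, p, shape=(4, 4)):
        return pv.PhasorField(np.full(shape, p.g), np.full(shape, p.s),
                              np.full(shape, 10.0), np.ones(shape, bool))

    def test_uniform_field_at_principal_point_has_its_hue(self, triangle_cmap):
        from matplotlib.colors import rgb_to_hsv
        p1 = triangle_cmap.principal_points[1]
        img = pv.render_image(self.uniform_field(p1), triangle_cmap)
        hsv = rgb_to_hsv(img)
        assert np.allclose(hsv[..., 0], 1 / 3, atol=1e-6)
        assert np.allclose(hsv[..., 2], 1.0)

    def test_log_and_linear_share_hue_saturation(self, triangle_cmap, omega80):
        spec = pv.SceneSpec(kind="crystals_in_solution", shape=(24, 24), seed=2)
        field = pv.compute_phasor_field(pv.simulate_stack(spec, n_bins=64))
        lin = pv.render_image(field, triangle_cmap, pv.RenderConfig())
        log = pv.render_image(field, triangle_cmap,
                              pv.RenderConfig(scale="log"))
        from matplotlib.colors import rgb_to_hsv
        hsv_lin = rgb_to_hsv(lin)
        hsv_log = rgb_to_hsv(log)
        bright = hsv_lin[..., 2] > 0.01  # hue of near-black pixels is noisy
        assert np.allclose(hsv_lin[..., 0][bright], hsv_log[..., 0][bright],
                           atol=1e-6)
        assert not np.allclose(hsv_lin[..., 2], hsv_log[..., 2])

    def test_empty_field_renders_background_with_warning(self, triangle_cmap):
        shape = (3, 3)
        f = pv.PhasorField(np.full(shape, np.nan), np.full(shape, np.nan),
                           np.zeros(shape), np.zeros(shape, bool))
        with pytest.warns(UserWarning, match="no valid"):
            img = pv.render_image(f, triangle_cmap)
        assert np.array_equal(img, np.zeros((3, 3, 3)))

    def test_two_region_scene_has_two_distinct_hues(self, omega80):
        spec = pv.SceneSpec(kind="crystals_in_solution", shape=(32, 32),
                            seed=4, n_blobs=3)
        scene = pv.build_scene(spec)
        field = pv.compute_phasor_field(
            pv.simulate_stack(scene, n_bins=128))
        p_sol = spec.species[0].phasor(omega80)
        p_cry = spec.species[1].phasor(omega80)
        cmap = pv.ColorMapConfig((p_sol, p_cry, pv.PhasorPoint(0.9, 0.2)))
        img = pv.render_image(field, cmap, pv.RenderConfig(scale="log"))
        from matplotlib.colors import rgb_to_hsv
        hues = rgb_to_hsv(img)[..., 0]
        pure_cry = scene.fractions[1] > 0.99
        pure_sol = scene.fractions[0] > 0.99

        def circ_median_offset(values, ref):
            # hue is cyclic: compare on the circle, not the line
            return np.median((values - ref + 0.5) % 1.0 - 0.5)

        off_cry = circ_median_offset(hues[pure_cry], pv.hue_of(p_cry, cmap))
        off_sol = circ_median_offset(hues[pure_sol], pv.hue_of(p_sol, cmap))
        assert abs(off_cry) < 0.05
        assert abs(off_sol) < 0.05
        d_hue = abs((pv.hue_of(p_cry, cmap) - pv.hue_of(p_sol, cmap)
                     + 0.5) % 1.0 - 0.5)
        assert d_hue > 0.1


def test_legend_samples_colormap_over_semicircle(triangle_cmap):
    leg = pv.render_legend(triangle_cmap, resolution=64)
    assert leg.shape == (64, 64, 3)
    assert np.array_equal(leg[0, 0], [0, 0, 0])  # outside the semicircle
    assert leg[32, 32].max() > 0  # inside is colored
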