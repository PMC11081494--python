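"""Strain-rate estimators, the decomposition identity, and shape metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimorph import kinematics as kin
from epimorph import synth


def movie_under(flow, n_cells=120, seed=1, t_end=4.0, dt=0.5):
    mesh = synth.generate_tessellation(n_cells, jitter=0.2, seed=seed)
    times = np.arange(0.0, t_end + dt / 2, dt)
    movie = synth.simulate_movie(mesh, flow, times)
    return synth.movie_to_trackset(movie), mesh


class TestTissueStrainRate:
    def test_rigid_translation_gives_zero(self):
        class Translate(synth.FlowField):
            def velocity(self, points, t):
                return np.tile([3.0, -2.0], (len(np.atleast_2d(points)), 1))

            def strain(self, points, t):
                return np.zeros((len(np.atleast_2d(points)), 2, 2))

        ts, mesh = movie_under(Translate())
        cid = mesh.interior_cells()[10]
        t = kin.tissue_strain_rate(ts, cid, 4)
        assert np.abs(t.matrix).max() < 1e-10

    def test_rigid_rotation_symmetric_part_vanishes(self):
        omega = 0.05  # rad/min
        rot = synth.UniformFlow(np.array([[0.0, -omega], [omega, 0.0]]),
                                origin=np.array([60.0, 40.0]))
        ts, mesh = movie_under(rot)
        cid = mesh.interior_cells()[10]
        t = kin.tissue_strain_rate(ts, cid, 4)
        assert np.abs(t.matrix).max() < 1e-4

    def test_pure_shear_recovered_within_5pct(self):
        flow = synth.UniformFlow(np.diag([0.02, -0.02]))
        ts, mesh = movie_under(flow)
        for cid in mesh.interior_cells()[::10]:
            t = kin.tissue_strain_rate(ts, cid, 4)
            assert t.exx == pytest.approx(0.02, rel=0.05)
            assert t.eyy == pytest.approx(-0.02, rel=0.05)
            assert abs(t.exy) < 1e-3

    def test_undefined_with_too_few_neighbours(self, affine_movie):
        movie, _ = affine_movie
        ts = synth.movie_to_trackset(movie)
        # a frame index outside any valid window
        cid = next(iter(ts.frames[0].cells))
        assert kin.tissue_strain_rate(ts, cid, 0) is None


class TestCellShapeStrainRate:
    def test_unchanged_cell_gives_zero(self):
        ts, mesh = movie_under(synth.UniformFlow())
        cid = mesh.interior_cells()[3]
        s = kin.cell_shape_strain_rate(ts, cid, 4)
        assert np.abs(s.matrix).max() < 1e-12

    def test_ap_exponential_scaling_recovered(self):
        flow = synth.UniformFlow(np.diag([0.01, 0.0]))
        ts, mesh = movie_under(flow)
        cid = mesh.interior_cells()[3]
        s = kin.cell_shape_strain_rate(ts, cid, 4)
        assert s.exx == pytest.approx(0.01, rel=1e-3)
        assert abs(s.eyy) < 1e-6 and abs(s.exy) < 1e-6

    def test_rigid_rotation_gives_zero(self):
        rot = synth.UniformFlow(np.array([[0.0, -0.05], [0.05, 0.0]]),
                                origin=np.array([60.0, 40.0]))
        ts, mesh = movie_under(rot)
        cid = mesh.interior_cells()[3]
        s = kin.cell_shape_strain_rate(ts, cid, 4)
        assert np.abs(s.matrix).max() < 1e-4

    def test_moment_fallback_on_pure_scaling(self):
        # strip vertex correspondence to exercise the second-moment log-map
        flow = synth.UniformFlow(np.diag([0.01, 0.0]))
        ts, mesh = movie_under(flow)
        for f in ts.frames:
            for c in f.cells.values():
                c.vertex_ids = None
        cid = mesh.interior_cells()[3]
        s = kin.cell_shape_strain_rate(ts, cid, 4)
        assert s.exx == pytest.approx(0.01, rel=0.01)
        assert abs(s.eyy) < 1e-4


class TestDecomposition:
    def test_identity_exact_by_construction(self, affine_movie):
        movie, _ = affine_movie
        ts = synth.movie_to_trackset(movie)
        cid = movie.meshes[0].interior_cells()[0]
        t = kin.tissue_strain_rate(ts, cid, 6)
        s = kin.cell_shape_strain_rate(ts, cid, 6)
        i = kin.intercalation_strain_rate(t, s)
        resid = t.matrix - s.matrix - i.matrix
        assert np.abs(resid).max() == 0.0

    def test_affine_flow_gives_no_intercalation(self, affine_movie):
        movie, _ = affine_movie
        ts = synth.movie_to_trackset(movie)
        mesh0 = movie.meshes[0]
        vals = []
        for cid in mesh0.interior_cells()[::5]:
            t = kin.tissue_strain_rate(ts, cid, 6)
            s = kin.cell_shape_strain_rate(ts, cid, 6)
            if t is None or s is None:
                continue
            vals.append(np.abs((t - s).matrix).max())
        assert vals and max(vals) < 1e-3

    def test_mismatched_domains_rejected(self):
        a = kin.StrainTensor2(0.1, 0.0, 0.0, time_min=1.0, domain_id=1)
        b = kin.StrainTensor2(0.1, 0.0, 0.0, time_min=1.0, domain_id=2)
        with pytest.raises(ValueError):
            kin.intercalation_strain_rate(a, b)


class TestAreaStrainRate:
    def test_constant_area_zero(self):
        ts, mesh = movie_under(synth.UniformFlow())
        assert kin.area_strain_rate(ts, mesh.interior_cells()[0], 4) == 0.0

    def test_exponential_growth_rate_recovered(self):
        flow = synth.UniformFlow(np.diag([0.015, 0.015]))
        ts, mesh = movie_under(flow)
        r = kin.area_strain_rate(ts, mesh.interior_cells()[0], 4)
        assert r == pytest.approx(0.03, rel=1e-3)  # trace of the flow

    def test_truncated_window_is_nan(self):
        ts, mesh = movie_under(synth.UniformFlow())
        assert np.isnan(kin.area_strain_rate(ts, mesh.interior_cells()[0], 0))


class TestProjection:
    def test_axis_projections(self):
        t = kin.StrainTensor2(0.02, 0.0, -0.02)
        assert t.project("ap") == pytest.approx(0.02)
        assert t.project("dv") == pytest.approx(-0.02)
        assert t.project((1, 1)) == pytest.approx(0.0, abs=1e-15)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-0.1, 0.1), st.floats(-0.1, 0.1), st.floats(-0.1, 0.1))
    def test_ap_plus_dv_equals_trace(self, exx, exy, eyy):
        t = kin.StrainTensor2(exx, exy, eyy)
        assert t.project("ap") + t.project("dv") == pytest.approx(t.trace,
                                                                  abs=1e-12)


def ellipse_polygon(a, b, angle_deg, n=256):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([a * np.cos(t), b * np.sin(t)])
    th = np.radians(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return pts @ rot.T


class TestShapeMetrics:
    def test_orientation_of_dv_and_ap_ellipses(self):
        dv = kin.ShapeEllipse.from_polygon(ellipse_polygon(1.0, 3.0, 0.0))
        ap = kin.ShapeEllipse.from_polygon(ellipse_polygon(3.0, 1.0, 0.0))
        assert kin.cell_orientation(dv) == pytest.approx(90.0, abs=1e-6)
        assert kin.cell_orientation(ap) == pytest.approx(0.0, abs=1e-6)

    def test_isotropic_orientation_undefined(self):
        circ = kin.ShapeEllipse.from_polygon(ellipse_polygon(2.0, 2.0, 0.0))
        assert np.isnan(kin.cell_orientation(circ))

    def test_random_orientations_average_45_degrees(self):
        rng = np.random.default_rng(42)
        angles = rng.uniform(0.0, 180.0, size=100_000)
        shapes = [kin.ShapeEllipse(3.0, 1.5, a) for a in angles]
        mean = np.mean([kin.cell_orientation(s) for s in shapes])
        assert mean == pytest.approx(45.0, abs=0.3)

    def test_axial_elongation_anchor_values(self):
        circle = kin.ShapeEllipse.from_polygon(ellipse_polygon(2.0, 2.0, 0.0))
        at45 = kin.ShapeEllipse(3.0, 1.0, 45.0)
        strong_dv = kin.ShapeEllipse(50.0, 1.0, 90.0)
        strong_ap = kin.ShapeEllipse(50.0, 1.0, 0.0)
        assert kin.axial_shape_elongation(circle) == pytest.approx(0.0, abs=1e-9)
        assert kin.axial_shape_elongation(at45) == pytest.approx(0.0, abs=1e-12)
        assert kin.axial_shape_elongation(strong_dv) > 0.95
        assert kin.axial_shape_elongation(strong_ap) < -0.95

    @settings(deadline=None, max_examples=50)
    @given(st.floats(1.01, 10.0), st.floats(0.0, 180.0))
    def test_axial_elongation_symmetries(self, aspect, angle):
        s = kin.ShapeEllipse(aspect, 1.0, angle)
        s90 = kin.ShapeEllipse(aspect, 1.0, (angle + 90.0) % 180.0)
        s180 = kin.ShapeEllipse(aspect, 1.0, (angle + 180.0) % 180.0)
        v = kin.axial_shape_elongation(s)
        assert kin.axial_shape_elongation(s90) == pytest.approx(-v, abs=1e-9)
        assert kin.axial_shape_elongation(s180) == pytest.approx(v, abs=1e-9)
        assert -1.0 <= v <= 1.0


class TestRateOfChange:
    def test_constant_and_linear_series(self):
        dt = 0.5
        const = kin.rate_of_change(np.full(10, 3.0), dt)
        assert np.nanmax(np.abs(const)) == 0.0
        t = np.arange(10) * dt
        lin = kin.rate_of_change(0.5 * t, dt)
        assert np.allclose(lin[2:-2], 0.5)
        assert np.isnan(lin[:2]).all() and np.isnan(lin[-2:]).all()

    def test_quadratic_matches_analytic_derivative(self):
        dt = 0.5
        t = np.arange(12) * dt
        series = 0.3 * t**2 - t
        rate = kin.rate_of_change(series, dt)
        expected = 0.6 * t - 1.0  # central difference exact for quadratics
        assert np.allclose(rate[2:-2], expected[2:-2])


def test_misalignment_projection_deficit():
    # a 15-degree misalignment costs at most 1 - cos(15 deg) = 3.4% of the
    # projected strain rate
    assert kin.projection_deficit_pct(15.0) == pytest.approx(3.4, abs=0.05)
    assert kin.projection_deficit_pct(0.0) == 0.0
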