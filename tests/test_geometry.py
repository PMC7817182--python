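"""Cell-space projection/confinement, nucleus exclusion, bounce rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from astersim.geometry import (CellSpace, NucleusObstacle, bounce_off_nucleus,
                               confinement_force, nucleus_exclusion_force,
                               project_to_surface)


@pytest.fixture(scope="module")
def tcell_space():
    return CellSpace(7.0, plane_fraction=0.9, corner_radius=1.0,
                     stiffness=100.0)


def dense_boundary(space, n=100_000):
    """Brute-force boundary sampling (independent projection oracle)."""
    pts = []
    if space.has_plane:
        cx, cy = space.corner_center
        rc = space.corner_radius
        xs = np.linspace(-cx, cx, n // 3)
        pts.append(np.stack([xs, np.full_like(xs, space.plane_y)], axis=1))
        th = np.linspace(-math.pi / 2, space.theta_u, n // 6)
        arc = np.stack([np.cos(th), np.sin(th)], axis=1) * rc
        pts.append(arc + [cx, cy])
        pts.append(arc * [-1, 1] + [-cx, cy])
        phi = np.linspace(space.theta_u, math.pi - space.theta_u, n // 3)
        pts.append(space.radius * np.stack([np.cos(phi), np.sin(phi)],
                                           axis=1))
    else:
        phi = np.linspace(0, 2 * math.pi, n, endpoint=False)
        pts.append(space.radius * np.stack([np.cos(phi), np.sin(phi)],
                                           axis=1))
    return np.concatenate(pts)


class TestCellSpace:
    def test_plane_fractions_store_and_place_the_plane(self):
        for pf, y in [(0.9, -5.6), (0.2, 4.2), (1.0, -7.0)]:
            sp = CellSpace(7.0, pf)
            assert sp.plane_fraction == pf
            assert sp.plane_y == pytest.approx(y)
        assert not CellSpace(7.0, 1.0).has_plane

    def test_projection_matches_plain_circle(self):
        sp = CellSpace(7.0, 1.0)
        rng = np.random.default_rng(0)
        p = rng.uniform(-10, 10, (200, 2))
        q, ins = sp.project(p)
        r = np.hypot(p[:, 0], p[:, 1])
        expect = p * (7.0 / r)[:, None]
        assert np.allclose(q, expect, atol=1e-9)
        assert (ins == (r <= 7.0)).all()

    def test_point_above_circle_projects_to_pole(self):
        q, inside = project_to_surface(CellSpace(7.0), (0.0, 8.0))
        assert not inside
        assert np.allclose(q, (0.0, 7.0))

    def test_center_projects_at_radius(self):
        q, inside = project_to_surface(CellSpace(7.0), (0.0, 0.0))
        assert inside
        assert math.hypot(*q) == pytest.approx(7.0)

    def test_projection_against_dense_sampling(self, tcell_space):
        """Closest point agrees with a brute-force boundary scan."""
        bnd = dense_boundary(tcell_space)
        rng = np.random.default_rng(1)
        pts = rng.uniform([-8, -8], [8, 8], (300, 2))
        q, _ = tcell_space.project(pts)
        d_claim = np.hypot(*(q - pts).T)
        d_true = np.min(np.hypot(pts[:, None, 0] - bnd[None, :, 0],
                                 pts[:, None, 1] - bnd[None, :, 1]), axis=1)
        assert np.allclose(d_claim, d_true, atol=2e-3)
        # and the claimed point lies on the boundary
        qq, _ = tcell_space.project(q)
        assert np.hypot(*(qq - q).T).max() < 1e-6

    def test_corner_tangency_is_continuous(self, tcell_space):
        """Fillet touches the plane and the circle tangentially."""
        sp = tcell_space
        cx, cy = sp.corner_center
        touch_plane = np.array([cx, sp.plane_y])
        assert math.hypot(*(touch_plane - sp.corner_center)) == \
            pytest.approx(sp.corner_radius)
        touch_circle = sp.corner_center * (sp.radius /
                                           (sp.radius - sp.corner_radius))
        assert math.hypot(*touch_circle) == pytest.approx(sp.radius)
        assert math.hypot(*(touch_circle - sp.corner_center)) == \
            pytest.approx(sp.corner_radius)

    def test_confinement_force_inside_zero_outside_linear(self, tcell_space):
        assert np.allclose(confinement_force(tcell_space, (0.0, 0.0)), 0.0)
        f = confinement_force(CellSpace(7.0, stiffness=100.0), (0.0, 8.0))
        assert np.allclose(f, (0.0, -100.0))

    def test_force_magnitude_equals_stiffness_times_distance(self,
                                                             tcell_space):
        bnd = dense_boundary(tcell_space)
        rng = np.random.default_rng(2)
        pts = rng.uniform([-9, -9], [9, 9], (1000, 2))
        outside = ~tcell_space.inside(pts)
        pts = pts[outside]
        f = tcell_space.confinement_force(pts)
        d_true = np.min(np.hypot(pts[:, None, 0] - bnd[None, :, 0],
                                 pts[:, None, 1] - bnd[None, :, 1]), axis=1)
        assert np.allclose(np.hypot(*f.T), tcell_space.stiffness * d_true,
                           rtol=0, atol=0.25)

    def test_force_vanishes_continuously_at_the_boundary(self, tcell_space):
        bnd = dense_boundary(tcell_space, n=6000)
        eps = 1e-6
        out = bnd * (1 + eps)  # radially nudged; only circle part is exact
        f = tcell_space.confinement_force(out)
        assert np.hypot(*f.T).max() < 0.01

    def test_synapse_points_uniform_arclength(self, tcell_space):
        pts = tcell_space.synapse_points(50)
        assert len(pts) == 50
        # all on the boundary
        q, _ = tcell_space.project(pts)
        assert np.hypot(*(q - pts).T).max() < 1e-9
        # equal arclength gaps: consecutive chord lengths match within
        # curvature corrections on the flat part
        flat = pts[np.abs(pts[:, 1] - tcell_space.plane_y) < 1e-9]
        gaps = np.diff(flat[:, 0])
        assert np.allclose(gaps, gaps[0], atol=1e-9)

    def test_no_synapse_raises(self):
        with pytest.raises(ValueError):
            CellSpace(7.0, 1.0).synapse_points(5)


class TestNucleus:
    def test_outside_zero_inside_linear(self):
        nuc = NucleusObstacle(radius=5.0, stiffness=100.0)
        assert np.allclose(nucleus_exclusion_force(nuc, (6.0, 0.0)), 0.0)
        f = nucleus_exclusion_force(nuc, (4.0, 0.0))
        assert np.allclose(f, (100.0, 0.0))

    def test_center_tie_break(self):
        nuc = NucleusObstacle(radius=5.0, stiffness=100.0)
        f = nucleus_exclusion_force(nuc, (0.0, 0.0))
        assert np.allclose(f, (500.0, 0.0))


class TestBounce:
    nuc = NucleusObstacle(radius=5.0, stiffness=100.0)

    def test_outside_step_unchanged(self):
        rng = np.random.default_rng(0)
        p = bounce_off_nucleus(self.nuc, np.array([6.0, 0]),
                               np.array([6.5, 0.5]), rng)
        assert np.allclose(p, (6.5, 0.5))

    def test_straight_crossing_reflects_specularly(self):
        # radial approach: reflection retraces the path beyond the entry
        rng = np.random.default_rng(0)
        p = bounce_off_nucleus(self.nuc, np.array([6.0, 0.0]),
                               np.array([4.5, 0.0]), rng)
        assert np.allclose(p, (5.5, 0.0), atol=1e-12)
        # path length from entry is preserved
        assert math.hypot(p[0] - 5.0, p[1]) == pytest.approx(0.5)

    def test_fallback_lands_on_the_edge(self):
        """With every candidate rejected (tight corner), the molecule is
        set to the edge of the nucleus."""
        rng = np.random.default_rng(0)
        p = bounce_off_nucleus(self.nuc, np.array([5.05, 0.0]),
                               np.array([4.0, 0.0]), rng,
                               max_attempts=1000,
                               accept=lambda q: False)
        assert math.hypot(*p) == pytest.approx(5.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_never_returns_point_inside_nucleus(self, seed):
        rng = np.random.default_rng(seed)
        ang = rng.uniform(0, 2 * math.pi)
        p_old = (5.0 + rng.uniform(0.001, 2.0)) \
            * np.array([math.cos(ang), math.sin(ang)])
        p_new = p_old + rng.normal(0, 1.0, 2)
        out = bounce_off_nucleus(self.nuc, p_old, p_new, rng)
        assert math.hypot(*out) >= 5.0 - 1e-9
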