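"""Confining geometry of the model T cell.

The cell is a disk of radius ``radius`` that may be truncated by a horizontal
plane (the immunological synapse).  ``plane_fraction`` is the fraction of the
full (2R) height that the truncated space retains; the space is the part of
the disk *above* the plane, so the synapse sits at the bottom:

    plane_y = radius * (1 - 2 * plane_fraction)

``plane_fraction = 0.9`` gives the polarizing T cell (flat side near the
bottom), ``plane_fraction = 0.2`` the small cap used to confine the
centrosome during initialization, and ``plane_fraction = 1`` a plain circle.

The sharp plane/circle junctions are replaced by circular fillets of radius
``corner_radius`` that are tangent to both the plane and the outer circle, so
the boundary has a continuous tangent everywhere.

All boundaries are elastic: a point outside the space is pulled back toward
its closest boundary point with a linear force (``stiffness`` in pN/µm).
Points strictly inside feel nothing.  The nucleus is a rigid disk that
excludes fibers and motors with the same linear law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellSpace",
    "NucleusObstacle",
    "project_to_surface",
    "confinement_force",
    "nucleus_exclusion_force",
    "bounce_off_nucleus",
]


class CellSpace:
    """Disk, optionally truncated by a plane, with tangent corner fillets."""

    def __init__(
        self,
        radius: float,
        plane_fraction: float = 1.0,
        corner_radius: float = 1.0,
        stiffness: float = 100.0,
    ):
        if radius <= 0:
            raise ValueError("radius must be positive")
        if not (0.0 < plane_fraction <= 1.0):
            raise ValueError("plane_fraction must be in (0, 1]")
        self.radius = float(radius)
        self.plane_fraction = float(plane_fraction)
        self.corner_radius = float(corner_radius)
        self.stiffness = float(stiffness)

        self.has_plane = plane_fraction < 1.0
        self.plane_y = radius * (1.0 - 2.0 * plane_fraction)
        if self.has_plane:
            if corner_radius <= 0:
                raise ValueError("corner_radius must be positive")
            rc = corner_radius
            cy = self.plane_y + rc
            lim = radius - rc
            if abs(cy) >= lim:
                raise ValueError(
                    "corner_radius too large for this plane_fraction")
            cx = math.sqrt(lim * lim - cy * cy)
            # center of the right corner fillet; the left one mirrors in x
            self.corner_center = np.array([cx, cy])
            # fillet arc spans directions (from its center) between straight
            # down (tangency with the plane) and the outward radial direction
            # (internal tangency with the outer circle)
            self.theta_u = math.atan2(cy, cx)
        else:
            self.corner_center = None
            self.theta_u = None

    # -- queries -----------------------------------------------------------

    def inside(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask, True where points are inside the space."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        r = np.hypot(p[:, 0], p[:, 1])
        ok = r <= self.radius
        if self.has_plane:
            ok &= p[:, 1] >= self.plane_y
            sx = np.abs(p[:, 0])
            d = np.stack([sx, p[:, 1]], axis=1) - self.corner_center
            theta = np.arctan2(d[:, 1], d[:, 0])
            in_wedge = (theta >= -0.5 * math.pi) & (theta <= self.theta_u)
            beyond = np.hypot(d[:, 0], d[:, 1]) > self.corner_radius
            ok &= ~(in_wedge & beyond)
        return ok

    def project(self, points: np.ndarray):
        """Closest boundary point for each input point.

        Returns ``(q, inside)`` with ``q`` of shape (n, 2).  Works for points
        on either side of the boundary.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        n = p.shape[0]
        sx = np.abs(p[:, 0])
        s = np.stack([sx, p[:, 1]], axis=1)
        r = np.hypot(s[:, 0], s[:, 1])

        # candidate 1: outer circle (tie-break at the exact center: +x axis)
        with np.errstate(invalid="ignore", divide="ignore"):
            qc = np.where(r[:, None] > 0, s * (self.radius / np.where(r == 0, 1, r))[:, None],
                          np.array([self.radius, 0.0]))
        if not self.has_plane:
            q = qc
        else:
            cand = [qc]
            valid = [np.arctan2(qc[:, 1], qc[:, 0]) >= self.theta_u]
            # candidate 2: flat synapse segment
            cx = self.corner_center[0]
            qf = np.stack([np.clip(s[:, 0], 0.0, cx),
                           np.full(n, self.plane_y)], axis=1)
            cand.append(qf)
            valid.append(np.ones(n, dtype=bool))
            # candidate 3: corner fillet arc
            d = s - self.corner_center
            theta = np.arctan2(d[:, 1], d[:, 0])
            theta = np.clip(theta, -0.5 * math.pi, self.theta_u)
            qk = self.corner_center + self.corner_radius * np.stack(
                [np.cos(theta), np.sin(theta)], axis=1)
            cand.append(qk)
            valid.append(np.ones(n, dtype=bool))

            dists = np.stack(
                [np.where(v, np.hypot(*(c - s).T), np.inf)
                 for c, v in zip(cand, valid)], axis=0)
            pick = np.argmin(dists, axis=0)
            q = np.choose(pick[:, None], cand)
        # unfold the x >= 0 half-plane
        sign = np.where(p[:, 0] < 0, -1.0, 1.0)
        q = np.stack([sign * q[:, 0], q[:, 1]], axis=1)
        return q, self.inside(p)

    def confinement_force(self, points: np.ndarray) -> np.ndarray:
        """Linear restoring force, zero inside the space."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        q, ins = self.project(p)
        f = self.stiffness * (q - p)
        f[ins] = 0.0
        return f

    # -- synapse contour ---------------------------------------------------

    def synapse_arclength(self) -> float:
        """Total arclength of the synapse contour (flat part + both fillets)."""
        if not self.has_plane:
            raise ValueError("space has no synapse (plane_fraction = 1)")
        wedge = self.theta_u + 0.5 * math.pi
        return 2.0 * self.corner_center[0] + 2.0 * self.corner_radius * wedge

    def synapse_points(self, n: int) -> np.ndarray:
        """``n`` points uniformly spaced by arclength along the synapse contour.

        The contour runs from the left fillet/circle tangency, along the left
        fillet, the flat segment, and the right fillet.  Points sit at the
        centers of ``n`` equal arclength bins, so the spacing is exactly
        uniform.
        """
        if not self.has_plane:
            raise ValueError("space has no synapse (plane_fraction = 1)")
        if n < 0:
            raise ValueError("n must be >= 0")
        total = self.synapse_arclength()
        s = (np.arange(n) + 0.5) * (total / n) if n else np.empty(0)
        return np.array([self._synapse_point_at(x) for x in s])

    def _synapse_point_at(self, s: float) -> np.ndarray:
        rc = self.corner_radius
        cx, cy = self.corner_center
        wedge = self.theta_u + 0.5 * math.pi
        arc = rc * wedge
        if s < arc:  # left fillet, from circle tangency down to the plane
            theta = math.pi - (self.theta_u - s / rc)
            return np.array([-cx + rc * math.cos(theta),
                             cy + rc * math.sin(theta)])
        s -= arc
        if s < 2.0 * cx:  # flat segment, left to right
            return np.array([-cx + s, self.plane_y])
        s -= 2.0 * cx
        theta = -0.5 * math.pi + s / rc  # right fillet, plane up to circle
        return np.array([cx + rc * math.cos(theta), cy + rc * math.sin(theta)])


@dataclass
class NucleusObstacle:
    """Rigid, immobile nuclear disk excluding fibers and motors."""

    center: np.ndarray = field(default_factory=lambda: np.zeros(2))
    radius: float = 5.0
    stiffness: float = 100.0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)

    def exclusion_force(self, points: np.ndarray) -> np.ndarray:
        """Outward linear force on points inside the disk, zero outside.

        At the exact center the outward direction is degenerate; the +x axis
        is used as the documented tie-break.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        d = p - self.center
        r = np.hypot(d[:, 0], d[:, 1])
        inside = r < self.radius
        with np.errstate(invalid="ignore", divide="ignore"):
            direction = np.where(r[:, None] > 0, d / np.where(r == 0, 1, r)[:, None],
                                 np.array([1.0, 0.0]))
        f = np.zeros_like(p)
        f[inside] = (self.stiffness * (self.radius - r[inside]))[:, None] \
            * direction[inside]
        return f

    def contains(self, point: np.ndarray) -> bool:
        return float(np.hypot(*(np.asarray(point) - self.center))) < self.radius


# -- scalar conveniences (spec-level operations) ---------------------------

def project_to_surface(space: CellSpace, p) -> tuple[np.ndarray, bool]:
    """Closest point on the boundary of ``space`` and an inside flag."""
    q, ins = space.project(np.asarray(p, dtype=float)[None, :])
    return q[0], bool(ins[0])


def confinement_force(space: CellSpace, p) -> np.ndarray:
    return space.confinement_force(np.asarray(p, dtype=float)[None, :])[0]


def nucleus_exclusion_force(nuc: NucleusObstacle, p) -> np.ndarray:
    return nuc.exclusion_force(np.asarray(p, dtype=float)[None, :])[0]


def bounce_off_nucleus(
    nuc: NucleusObstacle,
    p_old: np.ndarray,
    p_new: np.ndarray,
    rng: np.random.Generator,
    max_attempts: int = 1000,
    accept=None,
) -> np.ndarray:
    """Reflect a diffusive step off the nuclear disk.

    The first attempt is a specular reflection about the tangent at the entry
    point; if the reflected point is rejected (it lands back inside the
    nucleus, or fails the optional ``accept`` predicate — e.g. the molecule
    sits in a tight corner between nucleus and cell shape), random
    directions of the same remaining path length are tried.  After
    ``max_attempts`` failures the point is placed on the nucleus edge.
    """
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    c, R = nuc.center, nuc.radius
    if not nuc.contains(p_new):
        return p_new

    # entry point of the segment p_old -> p_new into the disk
    u = p_new - p_old
    a = u @ u
    if a == 0:
        return c + R * _safe_unit(p_old - c)
    b = 2.0 * (p_old - c) @ u
    cc = (p_old - c) @ (p_old - c) - R * R
    disc = max(b * b - 4 * a * cc, 0.0)
    t = (-b - math.sqrt(disc)) / (2 * a)
    t = min(max(t, 0.0), 1.0)
    entry = p_old + t * u
    normal = _safe_unit(entry - c)
    w = p_new - entry
    rem = math.hypot(*w)

    def ok(p):
        return not nuc.contains(p) and (accept is None or accept(p))

    cand = entry + (w - 2.0 * (w @ normal) * normal)
    if ok(cand):
        return cand
    for _ in range(max_attempts - 1):
        ang = rng.uniform(0.0, 2.0 * math.pi)
        cand = entry + rem * np.array([math.cos(ang), math.sin(ang)])
        if ok(cand):
            return cand
    # fallback: set to the edge of the nucleus
    return c + R * _safe_unit(p_new - c if (p_new != c).any() else normal)


def _safe_unit(v: np.ndarray) -> np.ndarray:
    n = math.hypot(*v)
    return v / n if n > 0 else np.array([1.0, 0.0])
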