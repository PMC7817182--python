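"""Microtubules as discretized semiflexible fibers on a rigid centrosome.

A fiber is an open polyline whose interior segments are held at the target
segment length (0.5 µm by default) by constraint projection; only the
terminal (plus-end) segment has a variable length, kept within
(0.5, 1.5] x target by re-segmentation as the fiber grows or shrinks.  The
bookkept contour ``length`` is authoritative; vertices are a discretization
of it.

Bending forces derive from the discrete curvature energy

    E = kappa / (2 ds^3) * sum_i |v_{i-1} - 2 v_i + v_{i+1}|^2

which is the standard worm-like-chain discretization; the uniform ``ds`` is
used for the terminal segment as well (the error is second order in the
terminal-length mismatch).

The centrosome is a rigid disk with ``n_anchors`` anchor directions spread
uniformly on the circle.  Each fiber minus end is tied to its anchor point
by a linear spring, and the first segment direction is clamped to the
body frame by a torsional spring (the "rotational elasticity"), so forces
on fibers are transmitted back to the body as force and torque.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FiberState",
    "Fiber",
    "Centrosome",
    "segment_count",
    "bending_forces",
    "bending_energy",
    "tip_load",
    "grow_or_shrink",
    "brownian_step",
    "ListFibers",
]


class FiberState(enum.IntEnum):
    GROWING = 0
    SHRINKING = 1
    PAUSED = 2


def segment_count(length: float, ds: float) -> int:
    """Number of segments for a contour length: terminal in (0.5, 1.5] ds."""
    return max(1, int(round(length / ds)))


@dataclass
class Fiber:
    """One microtubule: polyline vertices (minus end first) + bookkeeping."""

    vertices: np.ndarray
    target_segment_length: float = 0.5
    length: float = 0.0
    rigidity: float = 20.0          # pN µm^2
    state: FiberState = FiberState.GROWING
    id: int = 0

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.length == 0.0:
            segs = np.diff(self.vertices, axis=0)
            self.length = float(np.hypot(segs[:, 0], segs[:, 1]).sum())

    @classmethod
    def straight(cls, origin, direction, length, ds=0.5, **kw) -> "Fiber":
        origin = np.asarray(origin, dtype=float)
        d = np.asarray(direction, dtype=float)
        d = d / np.hypot(*d)
        m = segment_count(length, ds)
        s = np.minimum(np.arange(m + 1) * ds, length)
        s[-1] = length
        return cls(origin + s[:, None] * d, target_segment_length=ds,
                   length=float(length), **kw)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def contour_positions(self) -> np.ndarray:
        """Arclength position of each vertex along the bookkept contour."""
        n = self.n_vertices
        s = np.arange(n, dtype=float) * self.target_segment_length
        s[-1] = self.length
        return s

    def tip_tangent(self) -> np.ndarray:
        t = self.vertices[-1] - self.vertices[-2]
        n = np.hypot(*t)
        return t / n if n > 0 else np.array([1.0, 0.0])

    def point_at(self, abscissa: float) -> np.ndarray:
        """Point on the polyline at a contour position from the minus end."""
        s = self.contour_positions()
        a = min(max(abscissa, 0.0), self.length)
        return np.stack([np.interp(a, s, self.vertices[:, 0]),
                         np.interp(a, s, self.vertices[:, 1])])

    def tangent_at(self, abscissa: float) -> np.ndarray:
        s = self.contour_positions()
        i = min(int(np.searchsorted(s, abscissa, side="right")),
                self.n_vertices - 1)
        t = self.vertices[i] - self.vertices[i - 1]
        n = np.hypot(*t)
        return t / n if n > 0 else np.array([1.0, 0.0])


def bending_forces(fiber: Fiber) -> np.ndarray:
    """Per-vertex forces from the discrete curvature energy.

    Internal forces: the returned set has zero net force and zero net torque.
    Fibers with fewer than 3 vertices are straight by construction and get
    zero forces.
    """
    v = fiber.vertices
    n = len(v)
    f = np.zeros_like(v)
    if n < 3:
        return f
    ds = fiber.target_segment_length
    b = v[:-2] - 2.0 * v[1:-1] + v[2:]          # curvature vectors
    coef = -fiber.rigidity / ds ** 3
    f[:-2] += coef * b
    f[1:-1] += -2.0 * coef * b
    f[2:] += coef * b
    return f


def bending_energy(fiber: Fiber) -> float:
    v = fiber.vertices
    if len(v) < 3:
        return 0.0
    ds = fiber.target_segment_length
    b = v[:-2] - 2.0 * v[1:-1] + v[2:]
    return float(fiber.rigidity / (2.0 * ds ** 3) * (b * b).sum())


def tip_load(fiber: Fiber, force_on_tip) -> float:
    """Antagonistic load: the component of the tip force opposing growth."""
    t_hat = fiber.tip_tangent()
    return max(0.0, -float(np.dot(np.asarray(force_on_tip, dtype=float),
                                  t_hat)))


def grow_or_shrink(fiber: Fiber, delta_length: float,
                   min_length: float = 0.0) -> Fiber:
    """Extend the plus end along its tangent or retract along the contour.

    Shrinkage below ``min_length`` is clipped there.  The minus-end anchor
    vertex is untouched; interior vertices move only when re-segmentation
    requires resampling the tail.
    """
    old_L = fiber.length
    new_L = max(old_L + delta_length, min_length)
    if new_L == old_L:
        return fiber
    ds = fiber.target_segment_length
    s = fiber.contour_positions()
    if new_L > old_L:
        pts = np.vstack([fiber.vertices,
                         fiber.vertices[-1] + fiber.tip_tangent()
                         * (new_L - old_L)])
        cum = np.append(s, new_L)
    else:
        pts, cum = fiber.vertices, s
    m = segment_count(new_L, ds)
    targets = np.append(np.arange(m) * ds, new_L)
    newv = np.stack([np.interp(targets, cum, pts[:, 0]),
                     np.interp(targets, cum, pts[:, 1])], axis=1)
    return replace(fiber, vertices=newv, length=float(new_L))


@dataclass
class Centrosome:
    """Rigid body nucleating the aster; 90 uniform anchor directions."""

    center: np.ndarray = field(default_factory=lambda: np.zeros(2))
    orientation: float = 0.0
    body_radius: float = 0.5
    n_anchors: int = 90
    anchor_stiffness: float = 100.0       # pN/µm
    rotational_stiffness: float = 0.5     # pN µm/rad
    mobile: bool = False
    drag: float = 200.0                   # pN s/µm
    drag_rot: float = 500.0               # pN µm s

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)

    def anchor_angles(self) -> np.ndarray:
        return self.orientation + 2.0 * math.pi \
            * np.arange(self.n_anchors) / self.n_anchors

    def anchor_directions(self) -> np.ndarray:
        a = self.anchor_angles()
        return np.stack([np.cos(a), np.sin(a)], axis=1)

    def anchor_points(self) -> np.ndarray:
        return self.center + self.body_radius * self.anchor_directions()


def brownian_step(positions, forces, drag, dt, kT, rng):
    """One overdamped Langevin step:  x += dt/gamma F + sqrt(2 kT dt/gamma) xi.

    ``positions``/``forces`` are (..., 2); ``drag`` a scalar or broadcastable.
    """
    p = np.asarray(positions, dtype=float)
    f = np.asarray(forces, dtype=float)
    step = (dt / drag) * f
    if kT > 0:
        step = step + np.sqrt(2.0 * kT * dt / drag) * rng.standard_normal(
            p.shape)
    return p + step


class ListFibers:
    """Fiber access over plain :class:`Fiber` objects (reference path).

    Mirrors the array-backed access the engine uses, so motor operations can
    be unit-tested on hand-built fibers.
    """

    def __init__(self, fibers):
        self.fibers = list(fibers)

    def __len__(self):
        return len(self.fibers)

    def length(self, i) -> float:
        return self.fibers[i].length

    def state(self, i) -> FiberState:
        return self.fibers[i].state

    def set_state(self, i, state: FiberState):
        self.fibers[i] = replace(self.fibers[i], state=FiberState(state))

    def point_at(self, i, abscissa) -> np.ndarray:
        return self.fibers[i].point_at(abscissa)

    def tangent_at(self, i, abscissa) -> np.ndarray:
        return self.fibers[i].tangent_at(abscissa)

    def tip_point(self, i) -> np.ndarray:
        return self.fibers[i].vertices[-1]

    def nearest_point(self, p, radius):
        """Closest fiber point within ``radius`` of ``p``.

        Returns ``(fiber_index, abscissa, distance)`` or ``None``.
        """
        p = np.asarray(p, dtype=float)
        best = None
        for i, fb in enumerate(self.fibers):
            v = fb.vertices
            a, b = v[:-1], v[1:]
            ab = b - a
            denom = (ab * ab).sum(axis=1)
            t = np.clip(((p - a) * ab).sum(axis=1)
                        / np.where(denom == 0, 1.0, denom), 0.0, 1.0)
            proj = a + t[:, None] * ab
            d = np.hypot(*(proj - p).T)
            j = int(np.argmin(d))
            if d[j] <= radius and (best is None or d[j] < best[2]):
                s = fb.contour_positions()
                absc = float(s[j] + t[j] * (s[j + 1] - s[j]))
                best = (i, absc, float(d[j]))
        return best
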