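"""Overdamped Langevin engine advancing the whole system in lockstep.

All fiber vertices live in one padded array, so per-step mechanics are
vectorized across the aster.  Each timestep:

1. assemble point forces — elastic confinement by the cell boundary,
   nucleus exclusion, minus-end anchor and torsion springs (all linear
   springs toward known points, treated semi-implicitly for stability at
   dt = 0.01 s), and dynein link forces;
2. move vertices by the overdamped law with thermal noise, then apply the
   bending relaxation implicitly (a banded O(n) solve per fiber);
3. re-impose segment-length constraints by iterative projection
   (tolerance 1% of the segment length, at most 50 sweeps);
4. update the centrosome body (explicit, with its own drags) unless
   immobilized;
5. advance tip dynamics (force-dependent growth, catastrophe, shrinkage,
   forced re-nucleation at the minimum length);
6. advance KIF21B cappers and synapse dynein.

The per-vertex drag is ``drag_per_length * segment_length`` uniformly; the
same value enters the thermal noise, so free vertices diffuse with
D = kT / gamma.
"""

from __future__ import annotations

import math

import numpy as np

from . import dynein as dy
from . import kif21b as kf
from .fibers import Centrosome, FiberState, segment_count
from .geometry import CellSpace, NucleusObstacle
from .instability import Model, growth_speed, catastrophe_rate, \
    sample_initial_length
from .records import FrameRecord
from ._kernels import bend_implicit, project_segments

__all__ = ["System", "integrate_step"]


class ArrayFibers:
    """Fiber access over the engine's padded arrays (motor-facing view)."""

    def __init__(self, system: "System"):
        self.sys = system

    def __len__(self):
        return self.sys.n_fibers

    def length(self, i):
        return float(self.sys.L[i])

    def state(self, i):
        return FiberState(int(self.sys.fstate[i]))

    def set_state(self, i, state):
        self.sys.fstate[i] = int(state)

    def _contour(self, i):
        s = self.sys
        n = s.nv[i]
        pos = np.arange(n) * s.ds
        pos[-1] = s.L[i]
        return pos

    def point_at(self, i, abscissa):
        s = self.sys
        pos = self._contour(i)
        a = min(max(abscissa, 0.0), s.L[i])
        v = s.X[i, :s.nv[i]]
        return np.stack([np.interp(a, pos, v[:, 0]),
                         np.interp(a, pos, v[:, 1])])

    def tangent_at(self, i, abscissa):
        s = self.sys
        pos = self._contour(i)
        j = min(int(np.searchsorted(pos, abscissa, side="right")),
                s.nv[i] - 1)
        t = s.X[i, j] - s.X[i, j - 1]
        n = math.hypot(*t)
        return t / n if n > 0 else np.array([1.0, 0.0])

    def tip_point(self, i):
        return self.sys.X[i, self.sys.nv[i] - 1].copy()

    def nearest_point(self, p, radius):
        segs = self.sys._segments()
        if segs is None:
            return None
        a, b, fid, s0, slen = segs
        p = np.asarray(p, dtype=float)
        ab = b - a
        denom = (ab * ab).sum(axis=1)
        t = np.clip(((p - a) * ab).sum(axis=1)
                    / np.where(denom == 0, 1.0, denom), 0.0, 1.0)
        proj = a + t[:, None] * ab
        d2 = ((proj - p) ** 2).sum(axis=1)
        j = int(np.argmin(d2))
        d = math.sqrt(d2[j])
        if d > radius:
            return None
        return int(fid[j]), float(s0[j] + t[j] * slen[j]), d


class System:
    """Complete simulation state for one cell."""

    #: upper bound on any vertex relaxation speed (µm/s); physical motor
    #: and polymerization speeds are orders of magnitude slower
    RELAX_SPEED_CAP = 25.0

    def __init__(self, cfg, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.params = cfg.dynamics
        self.ds = cfg.segment_length
        self.n_fibers = cfg.n_fibers
        self.dt = cfg.dt
        self.time = 0.0
        self.phase = 1
        self.n_capper_releases = 0

        R = cfg.cell_radius
        self.space = CellSpace(R, 1.0, stiffness=cfg.boundary_stiffness)
        self.confine_space = CellSpace(
            R, cfg.plane_fraction_confine, cfg.corner_radius,
            cfg.boundary_stiffness)
        self.nucleus = NucleusObstacle(
            radius=cfg.nucleus_radius, stiffness=cfg.nucleus_stiffness)

        cap_center_y = 0.5 * (self.confine_space.plane_y + R)
        self.cen = Centrosome(
            center=np.array([0.0, cap_center_y]),
            body_radius=cfg.centrosome_body_radius,
            n_anchors=cfg.n_fibers,
            anchor_stiffness=cfg.anchor_stiffness,
            rotational_stiffness=cfg.rotational_stiffness,
            mobile=False,
            drag=cfg.centrosome_drag,
            drag_rot=cfg.centrosome_drag_rot)

        # padded fiber arrays
        F = self.n_fibers
        self.L = np.array([sample_initial_length(rng, self.params)
                           for _ in range(F)])
        self.fstate = np.zeros(F, dtype=np.int8)
        self._cap = int(max(self.L.max() / self.ds + 4, 8))
        self.X = np.zeros((F, self._cap, 2))
        self.nv = np.zeros(F, dtype=int)
        dirs = self.cen.anchor_directions()
        anchors = self.cen.anchor_points()
        for i in range(F):
            pts = self._initial_polyline(anchors[i], dirs[i], self.L[i])
            self.nv[i] = len(pts)
            self.X[i, :len(pts)] = pts

        # motors
        self.fibers_view = ArrayFibers(self)
        self.capper_params = cfg.capper
        self.cappers = [kf.CapperMotor(position=self._random_cytosol_point())
                        for _ in range(cfg.n_kif21b)]
        self.dynein_params = cfg.dynein
        self.dyneins: list[dy.DyneinCouple] = []

        self._gamma_v = cfg.drag_per_length * self.ds
        self._seg_cache = None

    # -- setup helpers -----------------------------------------------------

    def _initial_polyline(self, origin, direction, length):
        """March a nearly straight fiber, deflecting tangentially so the
        initial aster does not start inside the nucleus or the wall."""
        m = segment_count(length, self.ds)
        steps = np.full(m, self.ds)
        steps[-1] = length - (m - 1) * self.ds
        pts = [np.asarray(origin, dtype=float)]
        d = np.asarray(direction, dtype=float).copy()
        for h in steps:
            p = pts[-1]
            cand = p + h * d
            if self.nucleus.contains(cand):
                d = _tangential(p - self.nucleus.center, d)
                cand = p + h * d
            if not self.space.inside(cand[None, :])[0]:
                d = _tangential(cand, d)
                cand = p + h * d
            pts.append(cand)
        return np.array(pts)

    def _random_cytosol_point(self):
        R = self.cfg.cell_radius
        while True:
            p = self.rng.uniform(-R, R, 2)
            if self.space.inside(p[None, :])[0] \
                    and not self.nucleus.contains(p):
                return p

    def begin_phase2(self):
        """Swap in the synapse geometry, mobilize, attach dynein."""
        cfg = self.cfg
        self.space = CellSpace(cfg.cell_radius, cfg.plane_fraction_synapse,
                               cfg.corner_radius, cfg.boundary_stiffness)
        self.cen.mobile = True
        self.dyneins = dy.place_synapse_dynein(self.space, cfg.n_dynein)
        self.phase = 2

    @property
    def synapse_distance(self) -> float:
        """Centrosome-synapse distance along the vertical axis."""
        return float(self.cen.center[1] - self.space.plane_y)

    # -- per-step machinery ------------------------------------------------

    def _seg_targets(self, width=None):
        """Per-segment rest lengths (F, V-1) and the segment mask."""
        V = self.X.shape[1] if width is None else width
        m = self.nv - 1
        T = np.full((self.n_fibers, V - 1), self.ds)
        T[np.arange(self.n_fibers), m - 1] = self.L - (m - 1) * self.ds
        mask = np.arange(V - 1)[None, :] < m[:, None]
        return T, mask

    def _segments(self):
        if self._seg_cache is not None:
            return self._seg_cache
        T, mask = self._seg_targets()
        fidx, sidx = np.nonzero(mask)
        a = self.X[fidx, sidx]
        b = self.X[fidx, sidx + 1]
        s0 = sidx * self.ds
        slen = T[fidx, sidx]
        self._seg_cache = (a, b, fidx, s0, slen)
        return self._seg_cache

    def _ensure_capacity(self, need: int):
        if need <= self._cap:
            return
        new = max(need + 4, int(self._cap * 3 // 2))
        X = np.zeros((self.n_fibers, new, 2))
        X[:, :self._cap] = self.X
        self.X = X
        self._cap = new

    # -- the step ----------------------------------------------------------

    def step(self):
        cfg, dt, rng = self.cfg, self.dt, self.rng
        F = self.n_fibers
        V = int(self.nv.max())        # active padded width
        X = self.X[:, :V]
        valid = np.arange(V)[None, :] < self.nv[:, None]
        self._seg_cache = None

        E = np.zeros_like(X)            # explicit forces
        K = np.zeros((F, V))            # implicit spring stiffness
        KQ = np.zeros_like(X)           # stiffness * target point
        Fext = np.zeros_like(X)         # external forces (for tip load)

        # cell boundary confinement
        pts = X[valid]
        ins = self.space.inside(pts)
        if not ins.all():
            out_idx = np.nonzero(~ins)[0]
            q, _ = self.space.project(pts[out_idx])
            fi, vi = np.nonzero(valid)
            fi, vi = fi[out_idx], vi[out_idx]
            k = cfg.boundary_stiffness
            K[fi, vi] += k
            KQ[fi, vi] += k * q
            Fext[fi, vi] += k * (q - pts[out_idx])

        # nucleus exclusion
        r = np.hypot(X[..., 0], X[..., 1])
        in_nuc = valid & (r < self.nucleus.radius)
        if in_nuc.any():
            fi, vi = np.nonzero(in_nuc)
            p = X[fi, vi]
            rr = r[fi, vi]
            unit = np.where(rr[:, None] > 0,
                            p / np.where(rr == 0, 1, rr)[:, None],
                            np.array([1.0, 0.0]))
            qn = self.nucleus.radius * unit
            k = cfg.nucleus_stiffness
            K[fi, vi] += k
            KQ[fi, vi] += k * qn
            Fext[fi, vi] += k * (qn - p)

        # anchor + torsion springs (fiber side), reactions on the body
        anchors = self.cen.anchor_points()
        dirs = self.cen.anchor_directions()
        ka = self.cen.anchor_stiffness
        K[:, 0] += ka
        KQ[:, 0] += ka * anchors
        f_anchor = ka * (anchors - X[:, 0])
        kt = self.cen.rotational_stiffness / self.ds ** 2
        t_target = X[:, 0] + self.ds * dirs
        K[:, 1] += kt
        KQ[:, 1] += kt * t_target
        f_tors = kt * (t_target - X[:, 1])

        # dynein link forces
        self._apply_dynein_forces(E, K, KQ, Fext)

        # tip load before the move
        tipi = self.nv - 1
        tvec = X[np.arange(F), tipi] - X[np.arange(F), tipi - 1]
        tnorm = np.hypot(tvec[:, 0], tvec[:, 1])
        that = tvec / np.where(tnorm == 0, 1, tnorm)[:, None]
        ftip = Fext[np.arange(F), tipi]
        f_antag = np.maximum(0.0, -(ftip * that).sum(axis=1))

        # overdamped move: semi-implicit springs, implicit bending
        A = self._gamma_v / dt
        noise = math.sqrt(2.0 * cfg.kT * self._gamma_v / dt) \
            * rng.standard_normal(X.shape) if cfg.kT > 0 else 0.0
        Xn = (A * X + E + KQ + noise) / (A + K)[..., None]
        # cap the relaxation speed so stiff-spring transients (e.g. at the
        # phase shape change) relax over a few steps instead of jumping;
        # a speed cap (not a displacement cap) keeps the trajectory
        # consistent under timestep refinement
        disp = Xn - X
        dn = np.hypot(disp[..., 0], disp[..., 1])
        lim = self.RELAX_SPEED_CAP * dt
        scale = np.where(dn > lim, lim / np.where(dn == 0, 1, dn), 1.0)
        X[...] = np.where(valid[..., None], X + disp * scale[..., None], X)
        beta = dt * cfg.rigidity / (self._gamma_v * self.ds ** 3)
        bend_implicit(self.X, self.nv, beta)

        self._project_constraints()

        # centrosome body
        if self.cen.mobile:
            self._move_centrosome(f_anchor, f_tors, anchors)

        # tip dynamics
        self._step_tips(f_antag, that)

        # motors
        if self.cappers:
            self._step_cappers()
        if self.dyneins:
            self._step_dynein()

        self.time += dt

    def _project_constraints(self):
        """Re-impose segment lengths (1% tolerance, at most 50 sweeps)."""
        T, _ = self._seg_targets()
        tol = 0.01 * self.ds
        _, worst = project_segments(self.X, T, self.nv, tol, 50)
        if worst >= tol:
            raise RuntimeError(
                f"segment constraint projection failed to converge "
                f"(residual {worst:.3g} µm at t={self.time:.2f} s)")

    def _move_centrosome(self, f_anchor, f_tors, anchors):
        cfg, dt = self.cfg, self.dt
        c = self.cen.center
        Fc = -(f_anchor.sum(axis=0) + f_tors.sum(axis=0))
        # reaction torques about the center
        ra = anchors - c
        rt = self.X[:, 1] - c
        tau = float(-(ra[:, 0] * f_anchor[:, 1] - ra[:, 1] * f_anchor[:, 0]
                      ).sum()
                    - (rt[:, 0] * f_tors[:, 1] - rt[:, 1] * f_tors[:, 0]
                       ).sum())
        # confinement of the body center, steric exclusion by the nucleus
        q, ins = self.space.project(c[None, :])
        if not ins[0]:
            Fc = Fc + cfg.boundary_stiffness * (q[0] - c)
        rr = math.hypot(*c)
        reff = self.nucleus.radius + self.cen.body_radius
        if rr < reff:
            unit = c / rr if rr > 0 else np.array([1.0, 0.0])
            Fc = Fc + cfg.nucleus_stiffness * (reff - rr) * unit
        noise = math.sqrt(2.0 * cfg.kT * dt / self.cen.drag) \
            * self.rng.standard_normal(2) if cfg.kT > 0 else 0.0
        self.cen.center = c + (dt / self.cen.drag) * Fc + noise
        self.cen.orientation += (dt / self.cen.drag_rot) * tau

    def _step_tips(self, f_antag, that):
        p, dt, rng = self.params, self.dt, self.rng
        F = self.n_fibers
        grow = self.fstate == FiberState.GROWING
        shrink = self.fstate == FiberState.SHRINKING
        dL = np.zeros(F)
        v = np.zeros(F)
        if grow.any():
            v[grow] = growth_speed(f_antag[grow], p)
            dL[grow] = v[grow] * dt
        dL[shrink] = -p.v_s * dt

        # catastrophe after growth
        if grow.any():
            if p.model is Model.NON_PAUSING:
                k = np.full(grow.sum(), p.k_cat_const)
            else:
                k = catastrophe_rate(np.clip(v[grow], 0.0, p.v_g), p)
            cat = rng.random(grow.sum()) < -np.expm1(-k * dt)
            idx = np.nonzero(grow)[0][cat]
            self.fstate[idx] = FiberState.SHRINKING

        newL = self.L + dL
        renuc = shrink & (newL <= p.min_length)
        newL = np.maximum(newL, p.min_length)
        self.fstate[renuc] = FiberState.GROWING

        m_old = self.nv - 1
        m_new = np.maximum(1, np.round(newL / self.ds).astype(int))
        self._ensure_capacity(int(m_new.max()) + 1)
        fast = (m_new == m_old) & (dL != 0.0)
        tipi = self.nv - 1
        rows = np.nonzero(fast)[0]
        if rows.size:
            self.X[rows, tipi[rows]] += that[rows] * dL[rows][:, None]
        slow = np.nonzero((m_new != m_old) & (dL != 0.0))[0]
        for i in slow:
            self._resegment(i, float(newL[i]), int(m_new[i]))
        self.L = newL
        self._seg_cache = None

    def _resegment(self, i: int, new_L: float, m: int):
        old = self.X[i, :self.nv[i]]
        cum = np.arange(self.nv[i], dtype=float) * self.ds
        cum[-1] = self.L[i]
        if new_L > self.L[i]:
            t = old[-1] - old[-2]
            n = math.hypot(*t)
            t = t / n if n > 0 else np.array([1.0, 0.0])
            old = np.vstack([old, old[-1] + t * (new_L - self.L[i])])
            cum = np.append(cum, new_L)
        targets = np.append(np.arange(m) * self.ds, new_L)
        self.X[i, :m + 1, 0] = np.interp(targets, cum, old[:, 0])
        self.X[i, :m + 1, 1] = np.interp(targets, cum, old[:, 1])
        self.nv[i] = m + 1

    def _step_cappers(self):
        dt, rng = self.dt, self.rng
        fv, prm = self.fibers_view, self.capper_params
        for mot in self.cappers:
            if mot.state is kf.CapperState.FREE:
                prev = mot.position.copy()
                kf.diffuse(mot, dt, rng, self.space, self.nucleus, prm)
                kf.try_bind(mot, fv, dt, rng, prm, path_from=prev)
            elif mot.state is kf.CapperState.WALKING:
                if mot.abscissa > self.L[mot.fiber_id]:
                    mot.abscissa = float(self.L[mot.fiber_id])
                kf.walk(mot, fv, dt, rng, prm)
            elif mot.state is kf.CapperState.CAPPING:
                before = mot.pause_timer
                kf.tick_cap(mot, fv, self.cappers, dt)
                if before > 0 and mot.state is kf.CapperState.FREE:
                    self.n_capper_releases += 1

    def _apply_dynein_forces(self, E, K, KQ, Fext):
        """Add the link forces of bound couples to the force arrays."""
        if not self.dyneins:
            return
        prm = self.dynein_params
        for c in self.dyneins:
            if not c.bound or c.abscissa > self.L[c.fiber_id]:
                continue
            i = c.fiber_id
            mseg = min(int(c.abscissa // self.ds), self.nv[i] - 2)
            s0 = mseg * self.ds
            slen = self.L[i] - s0 if mseg == self.nv[i] - 2 else self.ds
            w = min(max((c.abscissa - s0) / slen, 0.0), 1.0)
            hand = (1 - w) * self.X[i, mseg] + w * self.X[i, mseg + 1]
            f = prm.link_stiffness * (c.anchor - hand)
            for vi, wt in ((mseg, 1 - w), (mseg + 1, w)):
                E[i, vi] += wt * f
                Fext[i, vi] += wt * f
                K[i, vi] += prm.link_stiffness * wt * wt
                KQ[i, vi] += prm.link_stiffness * wt * wt * self.X[i, vi]

    def _step_dynein(self):
        dt, rng, prm = self.dt, self.rng, self.dynein_params
        fv = self.fibers_view
        # walking / unbinding of bound hands
        for c in self.dyneins:
            if c.bound:
                dy.dynein_step(c, fv, dt, rng, prm)
        # binding of free hands to fibers near the synapse
        free = [ci for ci, c in enumerate(self.dyneins) if not c.bound]
        if not free:
            return
        segs = self._segments()
        if segs is None:
            return
        a, b, fid, s0, slen = segs
        band = self.space.plane_y + 1.0
        near = np.minimum(a[:, 1], b[:, 1]) <= band
        if not near.any():
            return
        a, b, fid, s0, slen = a[near], b[near], fid[near], s0[near], slen[near]
        anchors = np.array([self.dyneins[ci].anchor for ci in free])
        ab = b - a
        denom = (ab * ab).sum(axis=1)
        t = ((anchors[:, None, :] - a[None, :, :]) * ab[None, :, :]
             ).sum(axis=2) / np.where(denom == 0, 1.0, denom)[None, :]
        t = np.clip(t, 0.0, 1.0)
        proj = a[None, :, :] + t[..., None] * ab[None, :, :]
        d2 = ((proj - anchors[:, None, :]) ** 2).sum(axis=2)
        best = np.argmin(d2, axis=1)
        dist = np.sqrt(d2[np.arange(len(free)), best])
        p_bind = -math.expm1(-prm.binding_rate * dt)
        for k_, ci in enumerate(free):
            if dist[k_] <= prm.binding_radius \
                    and rng.random() < p_bind:
                j = best[k_]
                c = self.dyneins[ci]
                c.bound = True
                c.fiber_id = int(fid[j])
                c.abscissa = float(min(s0[j] + t[k_, j] * slen[j],
                                       self.L[fid[j]]))

    # -- recording ---------------------------------------------------------

    def record_frame(self, store_polylines: bool = False) -> FrameRecord:
        bound = [(c.fiber_id, c) for c in self.dyneins
                 if c.bound and c.abscissa <= self.L[c.fiber_id]]
        forces = []
        prm = self.dynein_params
        for i, c in bound:
            hand = self.fibers_view.point_at(i, c.abscissa)
            forces.append(-dy.spring_force_on_fiber(c, hand, prm))
        bound_ids = np.array([i for i, _ in bound], dtype=int)
        mt_l, mt_r = self._side_counts(np.unique(bound_ids))
        poly = [self.X[i, :self.nv[i]].copy()
                for i in range(self.n_fibers)] if store_polylines else None
        return FrameRecord(
            time=self.time, phase=self.phase,
            centrosome_center=self.cen.center.copy(),
            centrosome_orientation=float(self.cen.orientation),
            fiber_lengths=self.L.copy(),
            fiber_states=self.fstate.copy(),
            capper_states=np.array([int(m.state) for m in self.cappers]),
            dynein_bound_fiber_ids=bound_ids,
            dynein_forces=np.array(forces) if forces else np.empty((0, 2)),
            mt_left=mt_l, mt_right=mt_r,
            fiber_polylines=poly)

    def _side_counts(self, fiber_ids):
        """Dynein-bound fibers crossing the nucleus-center horizontal line,
        classified left/right by the x of the first crossing (x = 0: right).
        """
        y0 = float(self.nucleus.center[1])
        left = right = 0
        for i in fiber_ids:
            v = self.X[i, :self.nv[i]]
            dyv = v[:, 1] - y0
            sgn = np.signbit(dyv[:-1]) != np.signbit(dyv[1:])
            idx = np.nonzero(sgn)[0]
            if idx.size == 0:
                continue
            j = idx[0]
            denom = dyv[j + 1] - dyv[j]
            t = -dyv[j] / denom if denom != 0 else 0.0
            x = v[j, 0] + t * (v[j + 1, 0] - v[j, 0])
            if x < 0:
                left += 1
            else:
                right += 1
        return left, right


def _tangential(radial, d):
    """Deflect direction ``d`` to the tangent of a circular obstacle."""
    n = radial / max(math.hypot(*radial), 1e-12)
    t = np.array([-n[1], n[0]])
    if t @ d < 0:
        t = -t
    return t


def integrate_step(system: System, dt: float | None = None,
                   kT: float | None = None,
                   rng: np.random.Generator | None = None) -> System:
    """Advance the system by one timestep (spec-level entry point).

    ``dt``, ``kT`` and ``rng`` temporarily override the configured values.
    """
    old = (system.dt, system.cfg.kT, system.rng)
    try:
        if dt is not None:
            system.dt = dt
        if kT is not None:
            system.cfg.kT = kT
        if rng is not None:
            system.rng = rng
        system.step()
    finally:
        system.dt, system.cfg.kT, system.rng = old
    return system
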