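"""Two-state (plus pause) microtubule plus-end dynamics.

Growth is slowed exponentially by the antagonistic load on the tip,

    v(f) = v_g * exp(-f / f_g),

with ``f_g`` the characteristic force of polymerization.  The switch to
shrinkage (catastrophe) follows one of two models:

* ``NON_PAUSING`` — a constant, force-independent catastrophe rate
  ``k_cat_const`` (swept over 0.02-0.07 1/s in the length-control study);
* ``KIF21B_PAUSING`` — a force-dependent rate in which the mean catastrophe
  *time* interpolates linearly with the instantaneous growth speed between
  the free-growth value ``1/k_free`` and the stalled value ``1/k_stall``:

      1/k(v) = 1/k_stall + (1/k_free - 1/k_stall) * (v / v_g)

  so k(v_g) = k_free and k(0) = k_stall exactly.  The stalled rate is fixed
  at 0.3 1/s and ``k_free`` is calibrated so that 81% of freely growing tips
  survive a 3.3 s observation window without catastrophe, giving
  k_free = -ln(0.81)/3.3 ~= 0.0639 1/s.

Shrinkage proceeds at constant ``v_s`` down to ``min_length``, where the
fiber immediately re-enters the growth state (forced re-nucleation, keeping
the fiber count constant; there is no rescue).  A PAUSED tip (held by a
KIF21B capper) neither grows, shrinks, nor undergoes spontaneous
catastrophe; the capper's unbinding triggers shrinkage.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .fibers import Fiber, FiberState, grow_or_shrink

logger = logging.getLogger(__name__)

__all__ = [
    "Model",
    "DynamicsParams",
    "growth_speed",
    "catastrophe_rate",
    "step_tip",
    "sample_initial_length",
    "calibrate_free_rate",
    "calibrate_linear_relation",
    "barrier_survival_probability",
    "simulate_tip_survival",
    "simulate_network_1d",
]

#: stalled catastrophe rate (1/s), fixed by the fit to knockout dynamics
K_STALL = 0.3
#: free-tip survival constraint: fraction surviving, window (s)
SURVIVAL_FRACTION = 0.81
SURVIVAL_WINDOW = 3.3


class Model(str, enum.Enum):
    NON_PAUSING = "non_pausing"
    KIF21B_PAUSING = "kif21b_pausing"


def calibrate_free_rate(survival_fraction: float, window: float) -> float:
    """Zero-force catastrophe rate from an exponential survival constraint.

    Inverts  S = exp(-k * T):  k = -ln(S) / T.
    """
    if not (0.0 < survival_fraction <= 1.0):
        raise ValueError("survival_fraction must be in (0, 1]")
    if window <= 0:
        raise ValueError("window must be positive")
    return -math.log(survival_fraction) / window


K_FREE_DEFAULT = calibrate_free_rate(SURVIVAL_FRACTION, SURVIVAL_WINDOW)


@dataclass
class DynamicsParams:
    """Parameters of the plus-end model (lengths µm, times s, forces pN)."""

    v_g: float = 0.3            # free growth speed
    f_g: float = 4.0            # characteristic growing force
    v_s: float = 0.05           # shrinkage speed
    model: Model = Model.KIF21B_PAUSING
    k_cat_const: float = 0.045  # NON_PAUSING catastrophe rate
    k_free: float = K_FREE_DEFAULT
    k_stall: float = K_STALL
    pause_mean: float = 8.3     # mean capper-induced pause
    min_length: float = 0.1
    init_length_mean: float = 1.0

    def __post_init__(self):
        if isinstance(self.model, str):
            self.model = Model(self.model)
        if not (0.0 < self.k_free <= self.k_stall):
            raise ValueError("require 0 < k_free <= k_stall")
        if min(self.v_g, self.v_s, self.f_g, self.min_length) <= 0:
            raise ValueError("speeds, forces and lengths must be positive")


def growth_speed(f_antag, params: DynamicsParams):
    """Force-dependent growth speed v_g * exp(-f/f_g); accepts arrays."""
    return params.v_g * np.exp(-np.asarray(f_antag, dtype=float) / params.f_g)


def catastrophe_rate(v_inst, params: DynamicsParams):
    """Catastrophe rate at instantaneous growth speed ``v_inst``.

    NON_PAUSING ignores the speed.  KIF21B_PAUSING interpolates the mean
    catastrophe time linearly in v; speeds outside [0, v_g] are clipped
    (with a logged warning).
    """
    v = np.asarray(v_inst, dtype=float)
    if params.model is Model.NON_PAUSING:
        return np.broadcast_to(params.k_cat_const, v.shape).copy() \
            if v.shape else float(params.k_cat_const)
    if np.any(v < 0) or np.any(v > params.v_g * (1 + 1e-12)):
        logger.warning("growth speed outside [0, v_g]; clipping")
        v = np.clip(v, 0.0, params.v_g)
    inv = 1.0 / params.k_stall + (1.0 / params.k_free - 1.0 / params.k_stall) \
        * (v / params.v_g)
    out = 1.0 / inv
    return out if out.shape else float(out)


def sample_initial_length(rng: np.random.Generator,
                          params: DynamicsParams) -> float:
    """Exponential initial length (mean ``init_length_mean``), floored."""
    return max(params.min_length, rng.exponential(params.init_length_mean))


def step_tip(fiber: Fiber, f_antag: float, dt: float,
             rng: np.random.Generator, params: DynamicsParams) -> Fiber:
    """Advance one fiber tip by ``dt`` (reference single-fiber path).

    GROWING tips elongate at the force-dependent speed and may undergo
    catastrophe with probability 1 - exp(-k dt).  SHRINKING tips shorten at
    v_s and re-nucleate (switch back to growth) at ``min_length``.  PAUSED
    tips are inert: the capper alone ends a pause.
    """
    if fiber.state is FiberState.GROWING:
        v = float(growth_speed(f_antag, params))
        fiber = grow_or_shrink(fiber, v * dt)
        k = float(catastrophe_rate(v, params))
        if rng.random() < -math.expm1(-k * dt):
            fiber = replace(fiber, state=FiberState.SHRINKING)
    elif fiber.state is FiberState.SHRINKING:
        new_len = fiber.length - params.v_s * dt
        if new_len <= params.min_length:
            fiber = grow_or_shrink(
                fiber, params.min_length - fiber.length,
                min_length=params.min_length)
            fiber = replace(fiber, state=FiberState.GROWING)
        else:
            fiber = grow_or_shrink(fiber, -params.v_s * dt,
                                   min_length=params.min_length)
    return fiber


# -- calibration against an elastic barrier --------------------------------

def barrier_survival_probability(
    k_free: float,
    f_g: float,
    *,
    v_g: float = 0.3,
    k_stall: float = K_STALL,
    barrier_stiffness: float = 100.0,
    barrier_distance: float | None = None,
    window: float = SURVIVAL_WINDOW,
    dt: float = 1e-3,
) -> float:
    """Probability that a tip growing toward an elastic barrier survives.

    The tip starts ``barrier_distance`` (default 0.8 * v_g * window) from a
    linear barrier, grows at v(f) with f the instantaneous barrier load, and
    accumulates the catastrophe hazard of the pausing model.  The speed path
    is deterministic, so survival = exp(-integrated hazard).
    """
    if barrier_distance is None:
        barrier_distance = 0.8 * v_g * window
    p = DynamicsParams(v_g=v_g, f_g=f_g, k_free=k_free, k_stall=k_stall)
    x = 0.0
    hazard = 0.0
    for _ in range(int(round(window / dt))):
        f = barrier_stiffness * max(0.0, x - barrier_distance)
        v = float(growth_speed(f, p))
        hazard += float(catastrophe_rate(v, p)) * dt
        x += v * dt
    return math.exp(-hazard)


def calibrate_linear_relation(
    f_g_grid,
    *,
    survival_fraction: float = SURVIVAL_FRACTION,
    window: float = SURVIVAL_WINDOW,
    k_stall: float = K_STALL,
    v_g: float = 0.3,
    barrier_stiffness: float = 100.0,
    barrier_distance: float | None = None,
    tol: float = 1e-6,
):
    """Calibrate k_free against the barrier simulation for each f_g.

    For each characteristic force, finds by bisection the zero-force rate
    whose barrier-loaded survival over the observation window matches the
    constraint, then fits k_free linearly on f_g.  Infeasible rows (survival
    below target even at k_free -> 0, or above it at k_free = k_stall) are
    flagged with NaN.

    Returns ``(rows, fit)`` where rows is a list of dicts with keys
    ``f_g_pN``, ``k_free_per_s``, ``survival_check`` and fit is
    ``(slope, intercept)`` of the linear regression over feasible rows.
    """
    rows = []
    for f_g in f_g_grid:
        def surv(k):
            return barrier_survival_probability(
                k, f_g, v_g=v_g, k_stall=k_stall,
                barrier_stiffness=barrier_stiffness,
                barrier_distance=barrier_distance, window=window)

        lo, hi = 1e-9, k_stall
        if surv(lo) < survival_fraction or surv(hi) > survival_fraction:
            rows.append({"f_g_pN": float(f_g), "k_free_per_s": math.nan,
                         "survival_check": math.nan})
            continue
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if surv(mid) > survival_fraction:
                lo = mid
            else:
                hi = mid
        k = 0.5 * (lo + hi)
        rows.append({"f_g_pN": float(f_g), "k_free_per_s": k,
                     "survival_check": surv(k)})
    good = [(r["f_g_pN"], r["k_free_per_s"]) for r in rows
            if not math.isnan(r["k_free_per_s"])]
    fit = (math.nan, math.nan)
    if len(good) >= 2:
        xs, ys = zip(*good)
        slope, intercept = np.polyfit(xs, ys, 1)
        fit = (float(slope), float(intercept))
    return rows, fit


def simulate_tip_survival(
    rate: float,
    window: float,
    n_tips: int,
    rng: np.random.Generator,
    dt: float = 0.01,
) -> float:
    """Monte-Carlo fraction of tips with no catastrophe within ``window``.

    Tips grow at zero force with a constant hazard ``rate``; each timestep
    catastrophes independently with probability 1 - exp(-rate dt).
    """
    n_steps = int(round(window / dt))
    p = -math.expm1(-rate * dt)
    alive = np.ones(n_tips, dtype=bool)
    for _ in range(n_steps):
        alive &= rng.random(n_tips) >= p
    return float(alive.mean())


# -- 1D network surrogate ---------------------------------------------------

def simulate_network_1d(
    params: DynamicsParams,
    n_fibers: int,
    t_end: float,
    rng: np.random.Generator,
    dt: float = 0.01,
    n_cappers: int = 0,
    capper_cycle_extra: float = 2.0,
    record_interval: float = 0.4,
):
    """Length-only Monte Carlo of the tip rules, without mechanics.

    Serves as an independent oracle for steady-state mean length and for the
    qualitative effect of cappers.  Fibers grow force-free (f = 0), so the
    KIF21B_PAUSING rate is k_free throughout.  Cappers are modeled as a pool
    of ``n_cappers`` agents that each, after an idle period
    ``capper_cycle_extra`` (search + walk, exponential), caps a random
    growing fiber — chosen with probability proportional to its length, as
    diffusive binding to fiber mass dictates — holds it paused for an
    exponential time of mean ``pause_mean``, then triggers shrinkage.

    Returns ``(times, mean_lengths)`` arrays.
    """
    L = np.maximum(params.min_length,
                   rng.exponential(params.init_length_mean, n_fibers))
    state = np.zeros(n_fibers, dtype=np.int8)  # 0 grow, 1 shrink, 2 paused
    k_grow = (params.k_cat_const if params.model is Model.NON_PAUSING
              else params.k_free)
    p_cat = -math.expm1(-k_grow * dt)
    # capper agents: phase 0 idle, 1 capping; time left in phase
    c_phase = np.zeros(n_cappers, dtype=np.int8)
    c_timer = rng.exponential(capper_cycle_extra, n_cappers) if n_cappers else \
        np.empty(0)
    c_target = np.full(n_cappers, -1, dtype=int)

    n_steps = int(round(t_end / dt))
    every = max(1, int(round(record_interval / dt)))
    times, means = [], []
    for i in range(n_steps):
        grow = state == 0
        L[grow] += params.v_g * dt
        cat = grow & (rng.random(n_fibers) < p_cat)
        state[cat] = 1
        shrink = state == 1
        L[shrink] -= params.v_s * dt
        renuc = shrink & (L <= params.min_length)
        L[renuc] = params.min_length
        state[renuc] = 0
        if n_cappers:
            c_timer -= dt
            for j in np.flatnonzero(c_timer <= 0):
                if c_phase[j] == 0:  # try to cap a growing fiber
                    growing = np.flatnonzero(state == 0)
                    if growing.size:
                        w = L[growing] / L[growing].sum()
                        tgt = int(rng.choice(growing, p=w))
                        state[tgt] = 2
                        c_target[j] = tgt
                        c_phase[j] = 1
                        c_timer[j] = rng.exponential(params.pause_mean)
                    else:
                        c_timer[j] = rng.exponential(capper_cycle_extra)
                else:  # pause over: catastrophe, back to searching
                    if c_target[j] >= 0:
                        state[c_target[j]] = 1
                    c_target[j] = -1
                    c_phase[j] = 0
                    c_timer[j] = rng.exponential(capper_cycle_extra)
        if i % every == 0:
            times.append(i * dt)
            means.append(L.mean())
    return np.asarray(times), np.asarray(means)
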