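"""Synapse-anchored dynein couples that pull microtubules by sliding.

Fifty dynein motors sit at fixed anchors spread uniformly by arclength over
the synapse contour (the flat side of the polarizing cell plus its curved
corners).  An unbound couple binds the closest fiber point within its
binding radius at a first-order rate.  A bound hand walks toward the fiber
minus end with the linear force-velocity relation

    v = v_max * clamp(1 - f_opposing / f_stall, 0, 1)

where ``f_opposing`` is the component of the anchor-link spring force that
opposes minus-end-directed motion.  Because the anchor is fixed, walking
stretches the link and the spring force pulls the fiber (and through it the
centrosome) toward the synapse.  Unbinding is force-dependent (Kramers,
rate k_off0 * exp(|f|/f_unbind)); a hand reaching the minus end detaches.
Only sliding is modeled — there is no end-on capture or
depolymerization-coupled pulling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import CellSpace

__all__ = ["DyneinParams", "DyneinCouple", "place_synapse_dynein",
           "dynein_bind", "dynein_step", "collect_dynein_forces"]


@dataclass
class DyneinParams:
    v_max: float = 1.0            # µm/s, unloaded
    f_stall: float = 4.0          # pN
    k_off0: float = 0.1           # 1/s, unloaded
    f_unbind: float = 3.0         # pN, detachment force scale
    link_stiffness: float = 100.0  # pN/µm
    binding_radius: float = 0.05  # µm
    binding_rate: float = 5.0     # 1/s


@dataclass
class DyneinCouple:
    anchor: np.ndarray = field(default_factory=lambda: np.zeros(2))
    bound: bool = False
    fiber_id: int = -1
    abscissa: float = 0.0

    def __post_init__(self):
        self.anchor = np.asarray(self.anchor, dtype=float)


def place_synapse_dynein(space: CellSpace, n: int) -> list[DyneinCouple]:
    """``n`` couples uniformly spaced by arclength over the synapse contour."""
    if not space.has_plane:
        raise ValueError("space has no synapse (plane_fraction = 1)")
    return [DyneinCouple(anchor=p) for p in space.synapse_points(n)]


def dynein_bind(couple: DyneinCouple, fibers, dt: float,
                rng: np.random.Generator,
                params: DyneinParams) -> DyneinCouple:
    if couple.bound:
        return couple
    hit = fibers.nearest_point(couple.anchor, params.binding_radius)
    if hit is None:
        return couple
    if rng.random() < -math.expm1(-params.binding_rate * dt):
        couple.bound = True
        couple.fiber_id, couple.abscissa = hit[0], hit[1]
    return couple


def spring_force_on_fiber(couple: DyneinCouple, hand: np.ndarray,
                          params: DyneinParams) -> np.ndarray:
    """Link force applied to the fiber at the hand (points to the anchor)."""
    return params.link_stiffness * (couple.anchor - hand)


def dynein_step(couple: DyneinCouple, fibers, dt: float,
                rng: np.random.Generator, params: DyneinParams):
    """Advance one bound hand; returns ``(couple, force_on_fiber, hand)``.

    The force reported is the one applied to the fiber this step (zero if
    the couple ends the step unbound).
    """
    if not couple.bound:
        return couple, np.zeros(2), None
    i = couple.fiber_id
    length = fibers.length(i)
    if couple.abscissa > length:      # fiber shrank past the hand
        _release(couple)
        return couple, np.zeros(2), None
    hand = fibers.point_at(i, couple.abscissa)
    f = spring_force_on_fiber(couple, hand, params)
    fmag = float(np.hypot(*f))
    t_hat = fibers.tangent_at(i, couple.abscissa)
    f_opp = max(0.0, float(f @ t_hat))
    v = params.v_max * min(max(1.0 - f_opp / params.f_stall, 0.0), 1.0)
    couple.abscissa -= v * dt
    off = params.k_off0 * math.exp(min(fmag / params.f_unbind, 50.0))
    if couple.abscissa <= 0.0 or rng.random() < -math.expm1(-off * dt):
        _release(couple)
    return couple, f, hand


def collect_dynein_forces(couples, fibers, params: DyneinParams):
    """Instantaneous spring force experienced by each bound couple.

    The force on the anchor is minus the force applied to the fiber, so the
    set returned here balances the fiber-side forces exactly.
    """
    out = []
    for c in couples:
        if c.bound and c.abscissa <= fibers.length(c.fiber_id):
            hand = fibers.point_at(c.fiber_id, c.abscissa)
            out.append((c.anchor.copy(),
                        -spring_force_on_fiber(c, hand, params)))
    return out


def _release(couple: DyneinCouple):
    couple.bound = False
    couple.fiber_id = -1
    couple.abscissa = 0.0
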