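"""KIF21B motors: diffusing singles that cap and collapse microtubule tips.

Each motor cycles through three states.  FREE motors diffuse in the
cytosol (reflected at the cell boundary, bouncing off the nucleus) and can
bind a fiber passing within ``binding_radius``.  WALKING motors ride the
fiber toward the plus end at 0.77 µm/s (the measured single-molecule
speed), without exerting force.  On reaching the tip of a growing fiber the
motor becomes the fiber's CAPPER: the fiber is set to PAUSED and an
exponential pause timer of mean 8.3 s is drawn — redrawn fresh at capture,
so the pause length is independent of how long the motor has already
walked.  When the timer expires the capper unbinds, the fiber switches to
SHRINKING, and any other motors bound to that fiber unbind as well.

Only one motor caps a given fiber; a second motor arriving at a paused tip
waits there and is released by the collective-unbind rule.  A motor
arriving at the tip of a shrinking fiber unbinds without effect.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .fibers import FiberState
from .geometry import CellSpace, NucleusObstacle, bounce_off_nucleus

__all__ = ["CapperState", "CapperParams", "CapperMotor",
           "diffuse", "try_bind", "walk", "tick_cap", "release_cap"]


class CapperState(enum.IntEnum):
    FREE = 0
    WALKING = 1
    CAPPING = 2


@dataclass
class CapperParams:
    speed: float = 0.77             # µm/s, plus-end directed
    diffusion_coeff: float = 5.0    # µm^2/s
    binding_rate: float = 50.0      # 1/s within binding_radius
    binding_radius: float = 0.1     # µm
    unbind_rate_walking: float = 0.02  # 1/s; the motor is highly processive
    pause_mean: float = 8.3         # s


@dataclass
class CapperMotor:
    state: CapperState = CapperState.FREE
    position: np.ndarray = field(default_factory=lambda: np.zeros(2))
    fiber_id: int = -1
    abscissa: float = 0.0
    pause_timer: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)


def diffuse(motor: CapperMotor, dt: float, rng: np.random.Generator,
            space: CellSpace, nucleus: NucleusObstacle,
            params: CapperParams) -> CapperMotor:
    """Free diffusion with boundary reflection and nucleus bounce."""
    if motor.state is not CapperState.FREE or dt == 0.0:
        return motor
    old = motor.position
    new = old + math.sqrt(2.0 * params.diffusion_coeff * dt) \
        * rng.standard_normal(2)
    q, ins = space.project(new[None, :])
    if not ins[0]:
        new = 2.0 * q[0] - new          # specular for small steps
        if not space.inside(new[None, :])[0]:
            new = q[0]
    motor.position = bounce_off_nucleus(
        nucleus, old, new, rng,
        accept=lambda p: bool(space.inside(p[None, :])[0]))
    return motor


def try_bind(motor: CapperMotor, fibers, dt: float,
             rng: np.random.Generator, params: CapperParams,
             path_from: np.ndarray | None = None) -> CapperMotor:
    """Bind to the closest fiber encountered within the binding radius.

    When ``path_from`` is given, the diffusive path from that point to the
    current position is sampled at sub-steps as well, so a motor cannot
    tunnel through the thin capture band around a fiber in one timestep.
    """
    if motor.state is not CapperState.FREE:
        return motor
    probes = [motor.position]
    if path_from is not None:
        probes = [path_from + f * (motor.position - path_from)
                  for f in (0.25, 0.5, 0.75, 1.0)]
    hit = None
    for p in probes:
        hit = fibers.nearest_point(p, params.binding_radius)
        if hit is not None:
            break
    if hit is None:
        return motor
    if rng.random() < -math.expm1(-params.binding_rate * dt):
        i, absc, _ = hit
        motor.state = CapperState.WALKING
        motor.fiber_id = i
        motor.abscissa = absc
    return motor


def walk(motor: CapperMotor, fibers, dt: float, rng: np.random.Generator,
         params: CapperParams) -> CapperMotor:
    """Advance a walking motor; cap the fiber on reaching a growing tip."""
    if motor.state is not CapperState.WALKING:
        return motor
    i = motor.fiber_id
    if rng.random() < -math.expm1(-params.unbind_rate_walking * dt):
        _detach(motor, fibers.point_at(i, motor.abscissa))
        return motor
    motor.abscissa += params.speed * dt
    length = fibers.length(i)
    if motor.abscissa < length:
        return motor
    motor.abscissa = length
    st = fibers.state(i)
    if st is FiberState.GROWING:
        fibers.set_state(i, FiberState.PAUSED)
        motor.state = CapperState.CAPPING
        motor.pause_timer = rng.exponential(params.pause_mean)
    elif st is FiberState.SHRINKING:
        _detach(motor, fibers.tip_point(i))
    # PAUSED: another motor holds the cap; wait at the tip.
    return motor


def tick_cap(motor: CapperMotor, fibers, all_motors, dt: float) -> CapperMotor:
    """Run down the pause timer; on expiry release the cap."""
    if motor.state is not CapperState.CAPPING:
        return motor
    motor.pause_timer -= dt
    if motor.pause_timer <= 0.0:
        release_cap(motor, fibers, all_motors)
    return motor


def release_cap(motor: CapperMotor, fibers, all_motors) -> CapperMotor:
    """Expired cap: fiber to SHRINKING; every motor on the fiber unbinds."""
    if motor.state is not CapperState.CAPPING or motor.pause_timer > 0.0:
        return motor
    i = motor.fiber_id
    fibers.set_state(i, FiberState.SHRINKING)
    _detach(motor, fibers.tip_point(i))
    for other in all_motors:
        if other is not motor and other.state in (
                CapperState.WALKING, CapperState.CAPPING) \
                and other.fiber_id == i:
            _detach(other, fibers.point_at(i, other.abscissa))
    return motor


def _detach(motor: CapperMotor, position: np.ndarray):
    motor.state = CapperState.FREE
    motor.position = np.asarray(position, dtype=float).copy()
    motor.fiber_id = -1
    motor.abscissa = 0.0
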