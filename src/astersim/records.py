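"""Time-sampled system state: frames and trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameRecord", "Trajectory", "POLARIZED", "CENSORED"]

POLARIZED = "polarized"
CENSORED = "censored"


@dataclass
class FrameRecord:
    """One recorded frame (default cadence 0.4 s)."""

    time: float
    phase: int
    centrosome_center: np.ndarray
    centrosome_orientation: float
    fiber_lengths: np.ndarray
    fiber_states: np.ndarray
    capper_states: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    dynein_bound_fiber_ids: np.ndarray = field(
        default_factory=lambda: np.empty(0, int))
    dynein_forces: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2)))
    mt_left: int = 0
    mt_right: int = 0
    fiber_polylines: list | None = None


@dataclass
class Trajectory:
    """Frames of one run plus its polarization outcome."""

    frames: list
    outcome: str = CENSORED
    polarization_time: float | None = None  # since Phase II start; None if censored
    phase2_start: float = 0.0
    config: dict = field(default_factory=dict)
    seed: object = None

    def phase2_frames(self):
        return [f for f in self.frames if f.phase == 2]
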