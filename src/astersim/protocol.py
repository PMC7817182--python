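"""Two-phase simulation protocol, configuration, repeats and file output.

Phase I (default 300 s): the cell is a plain circle, the centrosome is
immobilized inside a small confinement cap on the side opposite the future
synapse, and the aster grows to a steady state from exponential initial
lengths (mean 1 µm).  Phase II (up to 800 s): the cell acquires a flat
synapse side with curved corners carrying 50 dynein couples, the centrosome
is released, and the run ends when the centrosome comes within 2.5 µm of
the synapse (polarized) or the time cap is reached (censored).

State is recorded every 0.4 s.  Repeats are independently seeded from a
root seed, so a run is bitwise reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynein import DyneinParams
from .engine import System
from .instability import DynamicsParams, Model
from .kif21b import CapperParams
from .records import CENSORED, POLARIZED, Trajectory

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "run_phase1", "run_phase2", "run_single",
           "run_experiment", "write_trajectory_csv", "load_config",
           "save_config"]


@dataclass
class SimulationConfig:
    """Every parameter of the model (lengths µm, times s, forces pN)."""

    # geometry
    cell_radius: float = 7.0
    plane_fraction_synapse: float = 0.9
    plane_fraction_confine: float = 0.2
    corner_radius: float = 1.0
    boundary_stiffness: float = 100.0
    nucleus_radius: float = 5.0
    nucleus_stiffness: float = 100.0
    # fibers / mechanics
    n_fibers: int = 90
    segment_length: float = 0.5
    rigidity: float = 20.0
    drag_per_length: float = 0.25
    kT: float = 0.00414
    dt: float = 0.01
    anchor_stiffness: float = 100.0
    rotational_stiffness: float = 0.5
    centrosome_body_radius: float = 0.5
    centrosome_drag: float = 200.0
    centrosome_drag_rot: float = 500.0
    # tip dynamics
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    # motors
    n_kif21b: int = 0
    capper: CapperParams = field(default_factory=CapperParams)
    n_dynein: int = 50
    dynein: DyneinParams = field(default_factory=DyneinParams)
    # protocol
    phase1_duration: float = 300.0
    phase2_max: float = 800.0
    polarization_threshold: float = 2.5
    record_interval: float = 0.4
    n_repeats: int = 30
    seed: int = 1
    store_polylines: bool = False

    def __post_init__(self):
        if isinstance(self.dynamics, dict):
            self.dynamics = DynamicsParams(**self.dynamics)
        if isinstance(self.capper, dict):
            self.capper = CapperParams(**self.capper)
        if isinstance(self.dynein, dict):
            self.dynein = DyneinParams(**self.dynein)
        if not (0 <= self.n_kif21b):
            raise ValueError("n_kif21b must be non-negative")
        # keep the capper pause in sync with the tip-dynamics pause
        self.capper.pause_mean = self.dynamics.pause_mean

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dynamics"]["model"] = self.dynamics.model.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    @property
    def synapse_plane_y(self) -> float:
        return self.cell_radius * (1.0 - 2.0 * self.plane_fraction_synapse)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: SimulationConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def _record_loop(system: System, cfg: SimulationConfig, duration: float,
                 frames: list, stop=None) -> bool:
    """Advance ``duration`` seconds, recording every record_interval.

    Returns True if ``stop`` fired (checked at each recording point).
    """
    per = max(1, int(round(cfg.record_interval / cfg.dt)))
    n_rec = int(round(duration / cfg.record_interval))
    for _ in range(n_rec):
        if stop is not None and stop():
            return True
        for _ in range(per):
            system.step()
        frames.append(system.record_frame(cfg.store_polylines))
    return stop() if stop is not None else False


def run_phase1(cfg: SimulationConfig, rng: np.random.Generator):
    """Initialize and advance Phase I; returns ``(system, frames)``."""
    system = System(cfg, rng)
    frames = [system.record_frame(cfg.store_polylines)]
    _record_loop(system, cfg, cfg.phase1_duration, frames)
    return system, frames


def run_phase2(system: System, cfg: SimulationConfig,
               phase1_frames=None) -> Trajectory:
    """Release the centrosome into the synapse geometry; run to outcome."""
    system.begin_phase2()
    t0 = system.time
    frames = list(phase1_frames or [])
    # the Phase-II transition frame supersedes a Phase-I frame recorded at
    # the same instant, keeping frame times strictly increasing
    if frames and abs(frames[-1].time - t0) < 0.5 * cfg.dt:
        frames.pop()
    frames.append(system.record_frame(cfg.store_polylines))

    def polarized():
        return system.synapse_distance < cfg.polarization_threshold

    done = _record_loop(system, cfg, cfg.phase2_max, frames, stop=polarized)
    if done:
        outcome, t_pol = POLARIZED, system.time - t0
    else:
        outcome, t_pol = CENSORED, None
    return Trajectory(frames=frames, outcome=outcome,
                      polarization_time=t_pol, phase2_start=t0,
                      config=cfg.to_dict())


def run_single(cfg: SimulationConfig, rng: np.random.Generator,
               phase2: bool = True) -> Trajectory:
    """One full run (Phase I, then optionally Phase II)."""
    system, frames = run_phase1(cfg, rng)
    if phase2:
        return run_phase2(system, cfg, phase1_frames=frames)
    return Trajectory(frames=frames, outcome=CENSORED,
                      polarization_time=None, phase2_start=system.time,
                      config=cfg.to_dict())


def run_experiment(cfg: SimulationConfig, n_repeats: int | None = None,
                   base_seed: int | None = None, out_dir=None,
                   phase2: bool = True) -> list[Trajectory]:
    """Independent seeded repeats; optionally writes CSVs and a manifest."""
    n_repeats = cfg.n_repeats if n_repeats is None else n_repeats
    base_seed = cfg.seed if base_seed is None else base_seed
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    trajs, manifest_runs = [], []
    for i in range(n_repeats):
        rng = np.random.default_rng([base_seed, i])
        t_start = _time.time()
        entry = {"repeat": i, "seed": [base_seed, i]}
        try:
            traj = run_single(cfg, rng, phase2=phase2)
            traj.seed = (base_seed, i)
            trajs.append(traj)
            entry.update(outcome=traj.outcome,
                         polarization_time=traj.polarization_time)
            if out_dir is not None:
                entry["file"] = f"traj_{i:03d}.csv"
                write_trajectory_csv(traj, out_dir / entry["file"])
        except RuntimeError as exc:          # integrator failure
            logger.error("repeat %d failed: %s", i, exc)
            entry.update(outcome="failed", error=str(exc))
        entry["wall_time_s"] = round(_time.time() - t_start, 2)
        manifest_runs.append(entry)
    if out_dir is not None:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump({"config": cfg.to_dict(), "runs": manifest_runs},
                      fh, indent=1)
    return trajs


def write_trajectory_csv(traj: Trajectory, path):
    """Long-format per-frame/per-fiber table plus a dynein side table."""
    rows = []
    for fr in traj.frames:
        for fid in range(len(fr.fiber_lengths)):
            rows.append((round(fr.time, 4), fr.phase,
                         fr.centrosome_center[0], fr.centrosome_center[1],
                         fid, fr.fiber_lengths[fid],
                         int(fr.fiber_states[fid])))
    pd.DataFrame(rows, columns=["time_s", "phase", "cx_um", "cy_um",
                                "fiber_id", "length_um", "state"]
                 ).to_csv(path, index=False)
    drows = []
    for fr in traj.frames:
        for k in range(len(fr.dynein_forces)):
            drows.append((round(fr.time, 4),
                          int(fr.dynein_bound_fiber_ids[k]),
                          fr.dynein_forces[k, 0], fr.dynein_forces[k, 1],
                          fr.mt_left, fr.mt_right))
    p = Path(path)
    pd.DataFrame(drows, columns=["time_s", "fiber_id", "fx_pN", "fy_pN",
                                 "mt_left", "mt_right"]
                 ).to_csv(p.with_name(p.stem + "_dynein.csv"), index=False)
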