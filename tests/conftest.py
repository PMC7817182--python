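"""Shared simulation fixtures.

The expensive study-condition runs are computed once per session and shared
by the acceptance tests: Phase-I runs provide steady-state lengths, and a
subset of the KIF21B-pausing systems is continued into Phase II for the
polarization-trend checks (the Phase-II continuation reuses the very same
steady states, as the two-phase protocol prescribes).
"""

from __future__ import annotations

import numpy as np
import pytest

from astersim.instability import Model
from astersim.protocol import SimulationConfig, run_phase1, run_phase2

N_SEEDS_PHASE1 = 5      # per condition, 300 s each
N_SEEDS_PHASE2 = 3      # continued into Phase II
PHASE2_CAP = 400.0      # s; scaled down from the full 800 s protocol


def study_config(model=Model.KIF21B_PAUSING, k_cat=None, n_kif21b=0):
    cfg = SimulationConfig()
    cfg.dynamics.model = model
    if k_cat is not None:
        cfg.dynamics.k_cat_const = k_cat
    cfg.n_kif21b = n_kif21b
    cfg.phase2_max = PHASE2_CAP
    cfg.__post_init__()
    return cfg


def _phase1_batch(make_cfg, n_seeds):
    out = []
    for seed in range(n_seeds):
        cfg = make_cfg()
        rng = np.random.default_rng([41_220, seed])
        system, frames = run_phase1(cfg, rng)
        out.append({"cfg": cfg, "system": system, "frames": frames,
                    "seed": seed})
    return out


@pytest.fixture(scope="session")
def nonpausing_runs():
    """Constant-catastrophe model at the sweep endpoints, 5 seeds each."""
    return {
        k: _phase1_batch(
            lambda k=k: study_config(Model.NON_PAUSING, k_cat=k),
            N_SEEDS_PHASE1)
        for k in (0.02, 0.07)
    }


@pytest.fixture(scope="session")
def pausing_runs():
    """KIF21B-pausing model with 0 vs 10 motors, 5 seeds each."""
    return {
        nk: _phase1_batch(
            lambda nk=nk: study_config(n_kif21b=nk), N_SEEDS_PHASE1)
        for nk in (0, 10)
    }


@pytest.fixture(scope="session")
def phase2_trajectories(pausing_runs):
    """Phase-II continuations of the first few pausing steady states."""
    out = {}
    for nk, batch in pausing_runs.items():
        trajs = []
        for entry in batch[:N_SEEDS_PHASE2]:
            traj = run_phase2(entry["system"], entry["cfg"],
                              phase1_frames=entry["frames"])
            trajs.append(traj)
        out[nk] = trajs
    return out


def steady_state_lengths(batch):
    """Mean MT length in the final Phase-I frame of each run."""
    return np.array([e["frames"][-1].fiber_lengths.mean() for e in batch])
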