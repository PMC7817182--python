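"""Derived quantities: lengths, polarization times, dynein force imbalance.

Force imbalance follows the normalized-asymmetry convention: with R and L
the summed magnitudes of the horizontal (x) dynein-force components
pointing right and left, the imbalance is |R - L| / (R + L), in [0, 1];
frames with no dynein force carry no value (NaN).

Dynein-bound microtubules are classified left/right of the cell's vertical
axis by the x-coordinate of the first crossing (from the minus end) of
their polyline with the horizontal line through the nucleus center; a
crossing exactly at x = 0 counts as right.
"""

from __future__ import annotations

import math

import numpy as np

from .records import POLARIZED, Trajectory

__all__ = ["mean_mt_length", "polarization_time", "force_imbalance",
           "crossing_side", "mt_side_counts", "early_side_stats",
           "smooth_series", "summarize_condition"]

UNDEFINED = math.nan


def mean_mt_length(frame) -> float:
    """Arithmetic mean contour length over the fibers of one frame."""
    return float(np.mean(frame.fiber_lengths))


def polarization_time(traj: Trajectory, threshold: float | None = None):
    """Seconds from Phase-II start to the first frame within threshold.

    Returns ``None`` when the trajectory is censored (never below the
    threshold within the recorded frames).
    """
    cfg = traj.config
    if threshold is None:
        threshold = cfg.get("polarization_threshold", 2.5)
    plane_y = cfg["cell_radius"] * (1.0 - 2.0 * cfg["plane_fraction_synapse"])
    for fr in traj.phase2_frames():
        if fr.centrosome_center[1] - plane_y < threshold:
            return fr.time - traj.phase2_start
    return None


def force_imbalance(frame) -> float:
    """|R - L| / (R + L) over horizontal dynein-force components."""
    fx = np.asarray(frame.dynein_forces)[:, 0] \
        if len(frame.dynein_forces) else np.empty(0)
    right = fx[fx > 0].sum()
    left = -fx[fx < 0].sum()
    total = right + left
    if total == 0:
        return UNDEFINED
    return float(abs(right - left) / total)


def crossing_side(polyline: np.ndarray, y0: float):
    """-1 (left), +1 (right) or None for a polyline vs the line y = y0.

    Uses the first crossing walking from the minus end; x = 0 maps to
    right (documented tie-break).
    """
    v = np.asarray(polyline, dtype=float)
    dy = v[:, 1] - y0
    flips = np.nonzero(np.signbit(dy[:-1]) != np.signbit(dy[1:]))[0]
    if flips.size == 0:
        return None
    j = flips[0]
    denom = dy[j + 1] - dy[j]
    t = -dy[j] / denom if denom != 0 else 0.0
    x = v[j, 0] + t * (v[j + 1, 0] - v[j, 0])
    return -1 if x < 0 else 1


def mt_side_counts(frame, nucleus) -> tuple[int, int]:
    """(MT_L, MT_R): dynein-bound fibers passing the nucleus on each side."""
    if frame.fiber_polylines is None:
        return frame.mt_left, frame.mt_right
    y0 = float(np.asarray(nucleus.center)[1])
    left = right = 0
    for i in np.unique(frame.dynein_bound_fiber_ids):
        side = crossing_side(frame.fiber_polylines[int(i)], y0)
        if side == -1:
            left += 1
        elif side == 1:
            right += 1
    return left, right


def early_side_stats(traj: Trajectory, window: float = 10.0) -> dict:
    """Mean bound-MT count and mean |MT_L - MT_R| early in Phase II."""
    totals, diffs = [], []
    for fr in traj.phase2_frames():
        if fr.time - traj.phase2_start > window:
            break
        totals.append(len(np.unique(fr.dynein_bound_fiber_ids)))
        diffs.append(abs(fr.mt_left - fr.mt_right))
    return {"mean_bound": float(np.mean(totals)) if totals else 0.0,
            "mean_side_diff": float(np.mean(diffs)) if diffs else 0.0,
            "n_frames": len(totals)}


def smooth_series(series, frames_per_window: int = 3):
    """Non-overlapping block means with a normal-approximation 95% CI.

    Returns ``(means, half_widths)`` over ``floor(N / window)`` blocks.
    """
    x = np.asarray(series, dtype=float)
    w = int(frames_per_window)
    if len(x) < w:
        raise ValueError("series shorter than the smoothing window")
    nb = len(x) // w
    blocks = x[:nb * w].reshape(nb, w)
    means = blocks.mean(axis=1)
    sd = blocks.std(axis=1, ddof=1) if w > 1 else np.zeros(nb)
    return means, 1.96 * sd / math.sqrt(w)


def summarize_condition(trajs, hist_bins=None) -> dict:
    """Per-condition aggregates used by the figures.

    Steady-state length is the mean MT length in the final Phase-I frame of
    each trajectory.  The force-imbalance histogram pools all defined
    per-frame values between Phase-II start and the polarization time (the
    full Phase II when censored), normalized to unit mass; the binning is
    part of the returned record.
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    if hist_bins is None:
        hist_bins = np.linspace(0.0, 1.0, 21)
    ss = []
    for t in trajs:
        p1 = [f for f in t.frames if f.phase == 1]
        if p1:
            ss.append(mean_mt_length(p1[-1]))
    times = [polarization_time(t) for t in trajs]
    observed = [x for x in times if x is not None]
    imb = []
    for t in trajs:
        t_pol = polarization_time(t)
        for fr in t.phase2_frames():
            if t_pol is not None and fr.time - t.phase2_start > t_pol:
                break
            v = force_imbalance(fr)
            if not math.isnan(v):
                imb.append(v)
    hist, edges = np.histogram(imb, bins=hist_bins)
    mass = hist / hist.sum() if hist.sum() else hist.astype(float)
    return {
        "n": len(trajs),
        "steady_state_length_mean": float(np.mean(ss)) if ss else math.nan,
        "steady_state_length_sd": float(np.std(ss, ddof=1))
        if len(ss) > 1 else 0.0,
        "single_trajectory": len(ss) == 1,
        "polarization_times": observed,
        "median_polarization_time": float(np.median(observed))
        if observed else math.nan,
        "censored_count": sum(1 for x in times if x is None),
        "imbalance_hist": mass,
        "imbalance_bin_edges": np.asarray(edges),
        "imbalance_values": np.asarray(imb),
    }
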