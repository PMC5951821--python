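"""Kinematic and behavioral statistics for reaching sessions.

Implements the task performance measures: hit rate of the cued pull
task, reaction time, trajectory straightness (SI), trial-to-trial
variability (RMSD around the trial-averaged trajectory), signed
lateral displacement of force-field trials, and windowed success-rate
curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CursorTrace


def hit_rate(hits: int, false_alarms: int) -> float:
    """Percentage of threshold pulls falling in the cued period.

    hit rate = hits / (hits + false alarms) x 100%.
    Raises ``ValueError`` when both counts are zero (undefined).
    """
    if hits < 0 or false_alarms < 0:
        raise ValueError("counts must be non-negative")
    total = hits + false_alarms
    if total == 0:
        raise ValueError("hit rate undefined: no pull events")
    return hits / total * 100.0


def reaction_time(
    cue_onset: float,
    trace: CursorTrace,
    threshold_position: float,
    cue_duration: float | None = None,
    axis: int = 1,
) -> float | None:
    """Milliseconds from cue onset to the first threshold crossing.

    The pull coordinate (``axis``, y by default) is compared against
    ``threshold_position`` (mm); the first sample at or after cue onset
    exceeding it defines the reaction.  Returns ``None`` if the
    threshold is never crossed within the cue period.
    """
    t_end = cue_onset + cue_duration if cue_duration is not None else trace.t0 + trace.duration
    seg = trace.window(cue_onset, t_end)
    if len(seg) == 0:
        return None
    above = seg[:, axis] > threshold_position
    idx = np.argmax(above)
    if not above[idx]:
        return None
    return idx / trace.rate * 1000.0


def path_length(points: np.ndarray) -> float:
    """Sum of Euclidean inter-sample distances along a trajectory."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 2:
        raise ValueError("trajectory needs at least two (x, y) points")
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def straightness_index(points: np.ndarray) -> float:
    """Start-to-end distance over path length, in (0, 1].

    SI = L_o / L_path where L_o is the Euclidean distance between the
    first and last point and L_path the summed inter-sample distances.
    Raises ``ValueError`` when the path has zero length (all points
    identical).
    """
    points = np.asarray(points, dtype=float)
    l_path = path_length(points)
    if l_path == 0:
        raise ValueError("straightness index undefined: zero path length")
    l_o = float(np.linalg.norm(points[-1] - points[0]))
    return l_o / l_path


def detect_movement_onset(
    trace: CursorTrace,
    t_reach_start: float,
    t_end: float,
    speed_threshold: float = 10.0,
    sustain_ms: float = 50.0,
) -> float | None:
    """First time the cursor speed stays above threshold for ``sustain_ms``.

    Speed is the finite-difference magnitude of the 2-D cursor velocity
    (mm/s).  Returns the onset time in seconds, or ``None`` if no
    sustained suprathreshold epoch exists in the reach period.
    """
    seg = trace.window(t_reach_start, t_end)
    if len(seg) < 2:
        return None
    speed = np.linalg.norm(np.diff(seg, axis=0), axis=1) * trace.rate  # mm/s
    n_sustain = max(int(round(sustain_ms / 1000.0 * trace.rate)), 1)
    above = speed > speed_threshold
    if len(above) < n_sustain:
        return None
    # run-length scan: first index opening a window of n_sustain True values
    windows = np.lib.stride_tricks.sliding_window_view(above, n_sustain)
    sustained = windows.all(axis=1)
    if not sustained.any():
        return None
    i0 = max(trace.index_at(t_reach_start), 0)
    onset_idx = i0 + int(np.argmax(sustained))
    return trace.t0 + onset_idx / trace.rate


@dataclass
class TrialVariabilityResult:
    mean_rmsd: float          # mm, averaged over trials
    per_trial_rmsd: np.ndarray
    n_trials_used: int
    n_excluded: int


def trial_variability(
    segments: list[np.ndarray],
    rate: float,
    onset_indices: list[int] | None = None,
    window_ms: tuple[float, float] = (-100.0, 500.0),
    coordinate: str = "x",
) -> TrialVariabilityResult:
    """Trial-to-trial RMSD of one coordinate around the mean trajectory.

    Each segment is an ``(N, 2)`` trajectory; ``onset_indices`` gives the
    sample index of movement onset within each segment (defaults to the
    first sample covering the window start).  Samples with onset-relative
    time t in ``[-100, +500]`` ms (inclusive) are compared: per trial,
    RMSD = sqrt(mean_t (x_t - xbar_t)^2) against the trial-averaged
    trajectory, and the mean RMSD across trials is returned.  Trials not
    covering the window are excluded with a warning.
    """
    if coordinate not in ("x", "y"):
        raise ValueError("coordinate must be 'x' or 'y'")
    col = 0 if coordinate == "x" else 1
    lo = int(round(window_ms[0] / 1000.0 * rate))
    hi = int(round(window_ms[1] / 1000.0 * rate))
    n_pts = hi - lo + 1  # inclusive window

    if onset_indices is None:
        onset_indices = [-lo] * len(segments)

    rows, n_excluded = [], 0
    for seg, onset in zip(segments, onset_indices):
        seg = np.asarray(seg, dtype=float)
        i0, i1 = onset + lo, onset + hi
        if i0 < 0 or i1 >= len(seg):
            n_excluded += 1
            continue
        rows.append(seg[i0 : i1 + 1, col])
    if n_excluded:
        warnings.warn(f"{n_excluded} trial(s) excluded: window not covered")
    if len(rows) < 2:
        raise ValueError("trial variability needs at least two trials covering the window")

    aligned = np.stack(rows)  # trials x n_pts
    assert aligned.shape[1] == n_pts
    mean_traj = aligned.mean(axis=0)
    per_trial = np.sqrt(np.mean((aligned - mean_traj) ** 2, axis=1))
    return TrialVariabilityResult(
        mean_rmsd=float(per_trial.mean()),
        per_trial_rmsd=per_trial,
        n_trials_used=len(rows),
        n_excluded=n_excluded,
    )


def x_displacement(points: np.ndarray, fixation_center_x: float = 0.0) -> float:
    """Signed lateral deviation of a reach, at its absolute maximum.

    Positive values point in the force-field push direction (+x).  The
    value is the x deviation from ``fixation_center_x`` whose absolute
    value is largest over the segment, keeping its sign, so force-field
    L-turns report positive peaks and washout aftereffects negative ones.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) == 0:
        raise ValueError("non-empty (N, 2) trajectory required")
    dev = points[:, 0] - fixation_center_x
    return float(dev[np.argmax(np.abs(dev))])


def block_success_curve(trials: pd.DataFrame, window: int = 10) -> pd.DataFrame:
    """Success percentage in consecutive non-overlapping trial windows.

    Returns a frame with columns ``window_start`` (trial index),
    ``n_trials``, ``percent`` and ``partial`` (True for a trailing
    window shorter than ``window``).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    outcomes = (trials["outcome"] == "success").to_numpy()
    rows = []
    for start in range(0, len(outcomes), window):
        chunk = outcomes[start : start + window]
        rows.append(
            {
                "window_start": start,
                "n_trials": len(chunk),
                "percent": float(chunk.mean() * 100.0),
                "partial": len(chunk) < window,
            }
        )
    return pd.DataFrame(rows, columns=["window_start", "n_trials", "percent", "partial"])


def session_metrics(
    trials: pd.DataFrame,
    trace: CursorTrace,
    successful_only: bool = True,
    window_ms: tuple[float, float] = (-100.0, 500.0),
) -> dict:
    """Per-session kinematic summary used by the pipeline drivers.

    Computes SI and x-displacement per reach plus mean RMSD per
    coordinate over the onset window, using successful trials only by
    default (matching how trajectory metrics are conditioned on reward).
    RMSD is computed within each target condition (trajectories to
    different targets are not averaged together) and the reported value
    is the trial-count-weighted mean over targets.
    """
    use = trials if not successful_only else trials[trials["outcome"] == "success"]
    segs, onsets, seg_targets, per_trial = [], [], [], []
    for _, tr in use.iterrows():
        seg = trace.window(tr["t_move_onset"] + window_ms[0] / 1000.0 - 0.05, tr["t_end"])
        if len(seg) < 2:
            continue
        onset_idx = trace.index_at(tr["t_move_onset"]) - max(
            trace.index_at(tr["t_move_onset"] + window_ms[0] / 1000.0 - 0.05), 0
        )
        segs.append(seg)
        onsets.append(onset_idx)
        seg_targets.append(tr["target"])
        reach = trace.window(tr["t_move_onset"], tr["t_end"])
        per_trial.append(
            {
                "trial_id": tr["trial_id"],
                "target": tr["target"],
                "si": straightness_index(reach) if len(reach) >= 2 else np.nan,
                "x_displacement": x_displacement(reach) if len(reach) else np.nan,
            }
        )
    out = {"per_trial": pd.DataFrame(per_trial), "n_trials_used": len(segs)}
    seg_targets = np.asarray(seg_targets)
    for coord in ("x", "y"):
        vals, weights = [], []
        for tgt in np.unique(seg_targets):
            sel = np.flatnonzero(seg_targets == tgt)
            if len(sel) < 2:
                continue
            try:
                res = trial_variability(
                    [segs[i] for i in sel], trace.rate,
                    [onsets[i] for i in sel], window_ms, coordinate=coord,
                )
                vals.append(res.mean_rmsd)
                weights.append(res.n_trials_used)
            except ValueError:
                pass
        out[f"rmsd_{coord}"] = float(np.average(vals, weights=weights)) if vals else np.nan
    return out
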