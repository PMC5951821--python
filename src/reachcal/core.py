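"""Shared data containers for the reaching / calcium-imaging pipeline.

Conventions used throughout the package:

* Behavioral (cursor/pole) positions are in millimetres in the hand
  workspace, sampled uniformly (1 kHz by default).  The y axis increases
  toward the animal, so a pull toward target 1 has positive Y velocity.
* Fluorescence traces are ROI x frame matrices sampled at the imaging
  frame rate (30 Hz by default); ROI centroids are in micrometres.
* Trial tables are plain :class:`pandas.DataFrame` objects with one row
  per trial (see :data:`TRIAL_COLUMNS`); all timestamps are seconds from
  session start.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Required columns of a trial table, one row per trial.
TRIAL_COLUMNS = (
    "trial_id",
    "block",
    "target",
    "outcome",
    "t_fix_start",
    "t_reach_start",
    "t_move_onset",
    "t_end",
)

#: Valid block labels for the adaptation task.
BLOCK_LABELS = ("baseline", "FF", "washout")


def validate_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Check a trial table's schema and ordering invariants.

    Returns the table unchanged.  Raises ``ValueError`` on missing
    columns, non-monotone within-trial timestamps or overlapping trials.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if len(trials) == 0:
        return trials
    t = trials
    ok = (
        (t["t_fix_start"] < t["t_reach_start"])
        & (t["t_reach_start"] <= t["t_move_onset"])
        & (t["t_move_onset"] < t["t_end"])
    )
    if not ok.all():
        bad = t.loc[~ok, "trial_id"].tolist()
        raise ValueError(f"non-monotone timestamps in trials {bad}")
    starts = t["t_fix_start"].to_numpy()
    ends = t["t_end"].to_numpy()
    if np.any(starts[1:] < ends[:-1]):
        raise ValueError("overlapping trial intervals")
    return trials


@dataclass
class CursorTrace:
    """Uniformly sampled 2-D cursor/pole position.

    Parameters
    ----------
    samples
        ``(N, 2)`` array of (x, y) positions in mm.
    rate
        Sampling rate in Hz.
    t0
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 2:
            raise ValueError("samples must have shape (N, 2)")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.rate

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def index_at(self, t: float) -> int:
        """Nearest sample index for time ``t`` (seconds)."""
        return int(round((t - self.t0) * self.rate))

    def window(self, t_start: float, t_end: float) -> np.ndarray:
        """Samples with ``t_start <= t < t_end``."""
        i0 = max(self.index_at(t_start), 0)
        i1 = min(self.index_at(t_end), len(self.samples))
        return self.samples[i0:i1]


@dataclass
class RoiTraceMatrix:
    """ROI x frame fluorescence with centroid coordinates.

    ``kind`` tracks whether the values are raw fluorescence (``raw_F``),
    relative change (``dFF``) or smoothed relative change
    (``denoised_dFF``); every transform that changes the meaning of the
    values must update it.
    """

    traces: np.ndarray
    rate: float
    kind: str = "raw_F"
    centroids: np.ndarray | None = None
    t0: float = 0.0

    _KINDS = ("raw_F", "dFF", "denoised_dFF")

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if self.centroids is not None:
            self.centroids = np.asarray(self.centroids, dtype=float)
            if self.centroids.shape != (self.traces.shape[0], 2):
                raise ValueError("centroids must have shape (n_rois, 2)")

    @property
    def n_rois(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.rate

    def frame_at(self, t: float) -> int:
        """Nearest frame index for time ``t`` (seconds)."""
        return int(round((t - self.t0) * self.rate))

    def with_traces(self, traces: np.ndarray, kind: str) -> "RoiTraceMatrix":
        return replace(self, traces=traces, kind=kind)


@dataclass
class ImageStack:
    """T x H x W image stack with frame rate and pixel size."""

    frames: np.ndarray
    rate: float
    pixel_size: float = 1.0  # µm per pixel

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (T, H, W)")
        if self.frames.shape[1] < 16 or self.frames.shape[2] < 16:
            raise ValueError("frames must be at least 16 x 16 pixels")
        if not self.rate > 0:
            raise ValueError("rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape


@dataclass
class ShiftSeries:
    """Per-frame rigid (dx, dy) shifts in pixels.

    ``dx`` is along image axis 1 (width / x), ``dy`` along axis 0
    (height / y).
    """

    shifts: np.ndarray
    pixel_size: float = 1.0  # µm per pixel

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must have shape (T, 2)")

    def __len__(self) -> int:
        return len(self.shifts)

    @property
    def dx(self) -> np.ndarray:
        return self.shifts[:, 0]

    @property
    def dy(self) -> np.ndarray:
        return self.shifts[:, 1]

    def in_um(self) -> np.ndarray:
        return self.shifts * self.pixel_size
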