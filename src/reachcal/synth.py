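"""Synthetic behavioral sessions, calcium traces and image stacks.

The generator stands in for unreleased raw data: it produces per-trial
tables with 1 kHz cursor traces, GCaMP6f-like ROI fluorescence at 30 Hz
with known direction tuning and block effects, and small rigid-jittered
image stacks — together with the ground truth needed for recovery
tests.  A single seed expands into independent substreams (behavior,
events, noise, jitter) so each component is reproducible on its own.

Timing model: the behavior clock (1 kHz) and imaging clock (30 Hz)
share t = 0 with zero offset; alignment between them is nearest-frame
lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import forcefield
from .core import CursorTrace, ImageStack, RoiTraceMatrix

#: The seven block-effect patterns: which of (baseline-FF, FF-washout,
#: baseline-washout) pairwise contrasts are significant.  Keys name the
#: per-block rate multipliers that induce each pattern.
BLOCK_PATTERNS = {
    "ff_up": {"baseline": 1.0, "FF": 3.0, "washout": 1.0},        # B-FF, FF-W
    "ff_down": {"baseline": 3.0, "FF": 1.0, "washout": 3.0},      # B-FF, FF-W
    "drift_up": {"baseline": 1.0, "FF": 2.0, "washout": 4.0},     # all three
    "washout_up": {"baseline": 1.0, "FF": 1.0, "washout": 3.0},   # FF-W, B-W
    "step_up": {"baseline": 1.0, "FF": 3.0, "washout": 3.0},      # B-FF, B-W
    "none": {"baseline": 1.0, "FF": 1.0, "washout": 1.0},
}


@dataclass
class SimConfig:
    """Parameters of the synthetic session generator.

    Defaults mirror the acquisition the pipeline targets: 1 kHz
    behavioral sampling, 30 Hz imaging of a 509 µm field, GCaMP6f-like
    kernel (50 ms rise, 600 ms decay).
    """

    n_trials: int = 100
    p_target2: float = 0.5
    p_fail: float = 0.1
    behavior_rate: float = 1000.0   # Hz
    imaging_rate: float = 30.0      # Hz
    n_rois: int = 30
    field_size: float = 509.0       # µm
    noise_sd: float = 0.05          # ΔF/F units
    pos_noise_sd: float = 0.2       # mm, additive on cursor position
    event_rate_base: float = 0.1    # events/s outside tuned windows
    tuning_gain: float = 8.0        # rate multiplier - 1 in preferred window
    block_effects: dict = dc_field(default_factory=dict)  # roi pattern -> multipliers
    kernel_rise: float = 50.0       # ms
    kernel_decay: float = 600.0     # ms
    jitter_sd: float = 1.0          # px
    reach_duration: float = 0.5     # s
    target_distance: float = 20.0   # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 0:
            raise ValueError("n_trials must be >= 0")
        if not 0.0 <= self.p_target2 <= 1.0:
            raise ValueError("p_target2 must be in [0, 1]")
        for name in ("behavior_rate", "imaging_rate", "kernel_rise", "kernel_decay"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("noise_sd", "pos_noise_sd", "event_rate_base", "tuning_gain", "jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def substreams(self) -> dict[str, np.random.Generator]:
        """Named independent RNG substreams derived from the seed."""
        root = np.random.SeedSequence(self.seed)
        names = ("behavior", "truth", "events", "noise", "jitter")
        children = root.spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def gen_ground_truth(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-ROI generative parameters: tuning, block pattern, centroid.

    Preferred target is 1, 2 or 0 (untuned), drawn 40/40/20%; block
    patterns are taken from ``config.block_effects`` if given (mapping
    pattern name -> fraction), else all ROIs get pattern ``"none"``.
    """
    rng = rng or config.substreams()["truth"]
    n = config.n_rois
    preferred = rng.choice([1, 2, 0], size=n, p=[0.4, 0.4, 0.2])
    if config.tuning_gain == 0:
        preferred = np.zeros(n, dtype=int)
    if config.block_effects:
        names = list(config.block_effects)
        probs = np.asarray([config.block_effects[k] for k in names], dtype=float)
        probs = probs / probs.sum()
        patterns = rng.choice(names, size=n, p=probs)
    else:
        patterns = np.array(["none"] * n)
    margin = 0.1 * config.field_size
    centroids = rng.uniform(margin, config.field_size - margin, size=(n, 2))
    return pd.DataFrame(
        {
            "roi": np.arange(n),
            "preferred_target": preferred,
            "true_dsi_sign": np.where(preferred == 1, 1, np.where(preferred == 2, -1, 0)),
            "block_pattern": patterns,
            "centroid_x": centroids[:, 0],
            "centroid_y": centroids[:, 1],
        }
    )


def _min_jerk_path(start, end, n):
    t = np.linspace(0.0, 1.0, n)
    s = 10 * t**3 - 15 * t**4 + 6 * t**5
    return np.asarray(start) + s[:, None] * (np.asarray(end) - np.asarray(start))


def gen_reaching_session(config: SimConfig) -> tuple[pd.DataFrame, CursorTrace]:
    """Simulate a two-target reaching session.

    Trials alternate fixation (cursor parked at the fixation center)
    and reach periods; reaches are minimum-jerk paths to the cued
    target (per-trial duration jittered ±15%) plus band-limited
    Gaussian positional noise (white noise smoothed with a 40 ms
    Gaussian kernel and rescaled to ``pos_noise_sd``, emulating
    physiological tremor — raw per-sample white noise at 1 kHz would
    dominate the path length and is not what a manipulandum records).
    A fraction ``p_fail`` of
    trials overshoot through the target and are labelled by checking
    whether the cursor actually held inside the target box; inter-trial
    intervals are 1.5 s after success and 3.5 s after failure.

    Target 1 lies at +``target_distance`` mm along y (a pull), target 2
    at the mirror position.
    """
    rng = config.substreams()["behavior"]
    rate = config.behavior_rate
    fix = np.array([0.0, 0.0])
    half = 4.0  # target half-width, mm
    hold_s = 0.3

    rows, chunks = [], []
    t = 0.0
    n_fix = int(round(0.8 * rate))
    n_hold = int(round(hold_s * rate))
    noise_sigma = 0.040 * rate  # 40 ms low-pass on the positional noise

    for trial_id in range(config.n_trials):
        target_id = 2 if rng.random() < config.p_target2 else 1
        sign = 1.0 if target_id == 1 else -1.0
        target = np.array([0.0, sign * config.target_distance])
        fail = rng.random() < config.p_fail
        # reaction period: cursor parked briefly after the target appears
        n_rt = int(round(rng.uniform(0.15, 0.35) * rate))
        n_reach = int(round(config.reach_duration * rng.uniform(0.85, 1.15) * rate))

        end = target * (1.35 if fail else 1.0)
        reach = _min_jerk_path(fix, end, n_reach)
        hold = np.tile(end, (n_hold, 1))
        seg = np.concatenate([np.tile(fix, (n_fix + n_rt, 1)), reach, hold])
        if config.pos_noise_sd > 0:
            white = rng.normal(0.0, 1.0, size=seg.shape)
            smooth = gaussian_filter1d(white, noise_sigma, axis=0)
            sd = smooth.std()
            if sd > 0:
                seg = seg + smooth * (config.pos_noise_sd / sd)

        # outcome from the generated trajectory: did the cursor hold
        # inside the target box for the final hold period?
        tail = seg[-n_hold:]
        held = np.all(np.abs(tail - target) <= half)
        outcome = "success" if held else "fail"

        t_fix_start = t
        t_reach_start = t + n_fix / rate
        t_move_onset = t_reach_start + n_rt / rate
        t_end = t_fix_start + len(seg) / rate
        iti = 1.5 if outcome == "success" else 3.5
        n_iti = int(round(iti * rate))
        chunks.extend([seg, np.tile(fix, (n_iti, 1))])
        t = t_end + n_iti / rate
        rows.append(
            {
                "trial_id": trial_id,
                "block": "baseline",
                "target": target_id,
                "outcome": outcome,
                "t_fix_start": t_fix_start,
                "t_reach_start": t_reach_start,
                "t_move_onset": t_move_onset,
                "t_end": t_end,
            }
        )

    samples = np.concatenate(chunks) if chunks else np.empty((0, 2))
    return pd.DataFrame(rows, columns=[
        "trial_id", "block", "target", "outcome",
        "t_fix_start", "t_reach_start", "t_move_onset", "t_end",
    ]), CursorTrace(samples, rate=rate)


def gen_adaptation_session(
    config: SimConfig,
    schedule: forcefield.BlockSchedule,
    controller: forcefield.ControllerParams | None = None,
    fieldp: forcefield.ForceFieldParams | None = None,
) -> tuple[pd.DataFrame, CursorTrace, dict]:
    """Simulate a force-field adaptation session via the reach simulator.

    Thin wrapper over :func:`reachcal.forcefield.simulate_schedule` that
    wires in the generator's seed substream and default parameters.
    """
    controller = controller or forcefield.ControllerParams()
    fieldp = fieldp or forcefield.ForceFieldParams()
    rng = config.substreams()["behavior"]
    return forcefield.simulate_schedule(
        schedule, controller, fieldp, rng,
        target=(0.0, config.target_distance), rate=config.behavior_rate,
    )


def calcium_kernel(rate: float, rise_ms: float, decay_ms: float, duration_s: float = 3.0) -> np.ndarray:
    """Difference-of-exponentials transient kernel, peak-normalized."""
    t = np.arange(0.0, duration_s, 1.0 / rate) * 1000.0  # ms
    k = np.exp(-t / decay_ms) - np.exp(-t / rise_ms)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel: decay must exceed rise")
    return k / peak


def gen_calcium_traces(
    trials: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimConfig,
    duration: float | None = None,
) -> RoiTraceMatrix:
    """Generate raw-F ROI traces tied to the behavioral session.

    Per ROI, event times follow an inhomogeneous Poisson process whose
    rate is ``event_rate_base`` everywhere, multiplied by
    ``1 + tuning_gain`` in a −1..+2 s window around movement onsets of
    the ROI's preferred target, and by the ROI's block-pattern
    multiplier throughout each trial's block.  Events (unit-mean
    exponential amplitudes) are convolved with the GCaMP-like kernel;
    a slow multiplicative drift and white noise are added on a positive
    baseline.
    """
    streams = config.substreams()
    ev_rng, noise_rng = streams["events"], streams["noise"]
    rate = config.imaging_rate
    if duration is None:
        duration = float(trials["t_end"].max() + 3.0) if len(trials) else 10.0
    if len(trials) and trials["t_end"].max() > duration:
        raise ValueError("trial timestamps exceed trace duration")
    n_frames = int(round(duration * rate))
    frame_t = np.arange(n_frames) / rate
    kernel = calcium_kernel(rate, config.kernel_rise, config.kernel_decay)

    # per-frame rate multipliers shared across ROIs with the same tuning
    window_mask = {}
    for tgt in (1, 2):
        mask = np.zeros(n_frames, dtype=bool)
        for onset in trials.loc[trials["target"] == tgt, "t_move_onset"]:
            mask |= (frame_t >= onset - 1.0) & (frame_t <= onset + 2.0)
        window_mask[tgt] = mask

    block_of_frame = np.full(n_frames, "", dtype=object)
    for _, tr in trials.iterrows():
        i0 = int(round(tr["t_fix_start"] * rate))
        i1 = int(round(tr["t_end"] * rate))
        block_of_frame[i0:i1] = tr["block"]

    baseline_f = 100.0
    traces = np.empty((config.n_rois, n_frames))
    dt = 1.0 / rate
    for i, roi in truth.iterrows():
        lam = np.full(n_frames, config.event_rate_base)
        pref = int(roi["preferred_target"])
        if pref in (1, 2) and config.tuning_gain > 0:
            lam = lam * np.where(window_mask[pref], 1.0 + config.tuning_gain, 1.0)
        mult = BLOCK_PATTERNS.get(str(roi["block_pattern"]), BLOCK_PATTERNS["none"])
        for label, m in mult.items():
            if m != 1.0:
                lam = np.where(block_of_frame == label, lam * m, lam)
        counts = ev_rng.poisson(lam * dt)
        amps = np.zeros(n_frames)
        nz = np.flatnonzero(counts)
        for j in nz:
            amps[j] = ev_rng.exponential(1.0, size=counts[j]).sum()
        signal = np.convolve(amps, kernel)[:n_frames]
        drift = 1.0 + 0.05 * np.sin(2 * np.pi * frame_t / 300.0 + noise_rng.uniform(0, 2 * np.pi))
        f = baseline_f * drift * (1.0 + signal)
        if config.noise_sd > 0:
            f = f + baseline_f * noise_rng.normal(0.0, config.noise_sd, size=n_frames)
        traces[i] = np.maximum(f, 0.0)

    centroids = truth[["centroid_x", "centroid_y"]].to_numpy()
    return RoiTraceMatrix(traces, rate=rate, kind="raw_F", centroids=centroids)


def gen_image_stack(
    truth: pd.DataFrame,
    traces: RoiTraceMatrix,
    config: SimConfig,
    size_px: int = 64,
    roi_sigma_px: float = 1.5,
    roi_amplitude: float = 40.0,
    background: float = 20.0,
    shot_noise: bool = True,
    n_frames: int | None = None,
) -> tuple[ImageStack, np.ndarray]:
    """Render an image stack from ROI footprints and their traces.

    Each frame is the sum of 2-D Gaussian footprints (centred at the
    ground-truth centroids, scaled to pixels) weighted by that frame's
    fluorescence, rigidly shifted by a smooth random jitter with
    stationary SD ``jitter_sd`` px, plus Poisson shot noise.  Returns
    the stack and the true per-frame (dx, dy) shifts for oracle tests.
    """
    from scipy import ndimage

    rng = config.substreams()["jitter"]
    pixel_size = config.field_size / size_px
    T = n_frames if n_frames is not None else traces.n_frames
    T = min(T, traces.n_frames)

    cent_px = truth[["centroid_x", "centroid_y"]].to_numpy() / pixel_size
    if np.any(cent_px < 0) or np.any(cent_px >= size_px):
        raise ValueError("ROI centroids fall outside the frame")

    yy, xx = np.mgrid[0:size_px, 0:size_px]
    footprints = np.stack(
        [
            np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * roi_sigma_px**2)))
            for cx, cy in cent_px
        ]
    )  # R x H x W

    if config.jitter_sd > 0:
        phi = 0.95
        innov = rng.normal(0.0, config.jitter_sd * np.sqrt(1 - phi**2), size=(T, 2))
        shifts = np.empty((T, 2))
        shifts[0] = 0.0
        for t in range(1, T):
            shifts[t] = phi * shifts[t - 1] + innov[t]
    else:
        shifts = np.zeros((T, 2))

    weights = traces.traces[:, :T] / 100.0 * roi_amplitude  # raw F -> image intensity
    frames = np.einsum("rt,rhw->thw", weights, footprints) + background
    for t in range(T):
        if shifts[t, 0] != 0 or shifts[t, 1] != 0:
            frames[t] = ndimage.shift(
                frames[t], (shifts[t, 1], shifts[t, 0]), order=1, mode="nearest"
            )
    if shot_noise:
        frames = rng.poisson(np.maximum(frames, 0.0)).astype(float)
    stack = ImageStack(frames, rate=traces.rate, pixel_size=pixel_size)
    return stack, shifts
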