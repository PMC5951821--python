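"""Image- and trace-level preprocessing for two-photon calcium movies.

Covers rigid motion correction by Fourier-domain cross-correlation,
shift quality control, running-percentile ΔF/F with edge padding,
skewness screening of ROI activity, and pixel-wise correlation maps.

The ΔF/F definition is

    ΔF/F(t) = (F(t) - F0(t)) / F0(t)

with ``F0(t)`` the running 8th percentile of the raw trace over a
centered 900-frame window (±15 s at 30 Hz).  Traces are first extended
by 450 frames on each side with the first/last value so that every
frame has a full window.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .core import ImageStack, ShiftSeries

DFF_PERCENTILE = 8.0
DFF_WINDOW_FRAMES = 900
DFF_PAD_FRAMES = 450


def estimate_rigid_shift(frame: np.ndarray, reference: np.ndarray) -> tuple[float, float]:
    """Sub-pixel rigid (dx, dy) translation of ``frame`` relative to ``reference``.

    The shift is estimated from the Fourier cross-power spectrum with
    upsampled sub-pixel refinement.  ``dx`` is along image axis 1 (x)
    and ``dy`` along axis 0 (y), signed as the displacement of the frame
    content: ``np.roll(reference, (3, -2), axis=(0, 1))`` yields
    ``(dx, dy) = (-2, 3)``.  Translating the frame back by
    ``(-dx, -dy)`` realigns it with the reference.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise ValueError("frame and reference must have the same shape")
    if np.ptp(frame) == 0 or np.ptp(reference) == 0:
        warnings.warn("flat image: shift set to (0, 0)")
        return (0.0, 0.0)
    # phase_cross_correlation returns the (row, col) shift that maps the
    # moving image onto the reference; negate to report frame displacement.
    shift, _, _ = phase_cross_correlation(reference, frame, upsample_factor=20, normalization=None)
    dy, dx = -shift[0], -shift[1]
    return (float(dx), float(dy))


def apply_shift(frame: np.ndarray, dx: float, dy: float, fill: float | None = None) -> np.ndarray:
    """Translate a frame by (dx, dy) pixels, filling exposed edges.

    ``fill`` defaults to the frame median.
    """
    if fill is None:
        fill = float(np.median(frame))
    return ndimage.shift(frame, (dy, dx), order=1, mode="constant", cval=fill)


def correct_motion(
    stack: ImageStack, reference: str | np.ndarray = "mean"
) -> tuple[ImageStack, ShiftSeries]:
    """Rigidly realign every frame to a reference image.

    ``reference`` may be ``"mean"`` (time-average of the stack),
    ``"first"``, or an explicit image.  Each frame is translated by its
    negated estimated shift; exposed edge pixels are filled with the
    frame median.  Returns the corrected stack and the estimated
    per-frame shifts (the displacements that were removed).
    """
    if stack.n_frames < 2:
        raise ValueError("motion correction needs at least two frames")
    if isinstance(reference, str):
        if reference == "mean":
            ref = stack.frames.mean(axis=0)
        elif reference == "first":
            ref = stack.frames[0]
        else:
            raise ValueError("reference must be 'mean', 'first' or an image")
    else:
        ref = np.asarray(reference, dtype=float)

    shifts = np.empty((stack.n_frames, 2))
    corrected = np.empty_like(stack.frames)
    for t in range(stack.n_frames):
        dx, dy = estimate_rigid_shift(stack.frames[t], ref)
        shifts[t] = (dx, dy)
        corrected[t] = apply_shift(stack.frames[t], -dx, -dy)
    out = ImageStack(corrected, rate=stack.rate, pixel_size=stack.pixel_size)
    return out, ShiftSeries(shifts, pixel_size=stack.pixel_size)


def shift_sd_qc(
    shifts: ShiftSeries, rate: float, epochs: list[tuple[float, float]] | None = None
) -> dict:
    """Standard deviation of x and y shifts, overall and within epochs.

    ``epochs`` are (start, end) times in seconds (e.g. task-performance
    periods around movement); their union selects the frames for the
    epoch-restricted SDs.  Values are in µm via the series' pixel size.
    """
    um = shifts.in_um()
    out = {
        "sd_x_um": float(np.std(um[:, 0])),
        "sd_y_um": float(np.std(um[:, 1])),
        "n_frames": len(shifts),
    }
    if epochs:
        t = np.arange(len(shifts)) / rate
        mask = np.zeros(len(shifts), dtype=bool)
        for t0, t1 in epochs:
            mask |= (t >= t0) & (t < t1)
        if mask.any():
            out["epoch_sd_x_um"] = float(np.std(um[mask, 0]))
            out["epoch_sd_y_um"] = float(np.std(um[mask, 1]))
            out["epoch_n_frames"] = int(mask.sum())
    return out


def pad_trace(trace: np.ndarray, pad_frames: int = DFF_PAD_FRAMES) -> np.ndarray:
    """Extend a trace with constant first/last values on both sides."""
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or len(trace) == 0:
        raise ValueError("trace must be a non-empty 1-D array")
    if pad_frames == 0:
        return trace.copy()
    return np.concatenate(
        [np.full(pad_frames, trace[0]), trace, np.full(pad_frames, trace[-1])]
    )


def running_percentile_baseline(
    trace: np.ndarray,
    percentile: float = DFF_PERCENTILE,
    window_frames: int = DFF_WINDOW_FRAMES,
) -> np.ndarray:
    """F0(t): running percentile over a centered window of padded F.

    The window at output frame ``t`` covers padded frames
    ``[t, t + window_frames)``, i.e. ``window_frames/2`` frames on each
    side of ``t`` in original coordinates.
    """
    if window_frames % 2 != 0:
        raise ValueError("window_frames must be even")
    padded = pad_trace(trace, window_frames // 2)
    windows = np.lib.stride_tricks.sliding_window_view(padded, window_frames)
    # window t covers padded [t, t + W), i.e. original [t - W/2, t + W/2)
    return np.percentile(windows[: len(np.atleast_1d(trace))], percentile, axis=-1)


def compute_dff(
    trace: np.ndarray,
    percentile: float = DFF_PERCENTILE,
    window_frames: int = DFF_WINDOW_FRAMES,
) -> np.ndarray:
    """ΔF/F with a running-percentile baseline.

    Raises ``ValueError`` naming the offending frames if any baseline
    value is non-positive (ΔF/F would be undefined).
    """
    trace = np.asarray(trace, dtype=float)
    f0 = running_percentile_baseline(trace, percentile, window_frames)
    bad = np.flatnonzero(f0 <= 0)
    if bad.size:
        head = bad[:10].tolist()
        raise ValueError(f"non-positive baseline F0 at {bad.size} frame(s), first {head}")
    return (trace - f0) / f0


def compute_dff_matrix(
    traces: np.ndarray,
    percentile: float = DFF_PERCENTILE,
    window_frames: int = DFF_WINDOW_FRAMES,
    denoise: bool = False,
) -> np.ndarray:
    """Row-wise ΔF/F of an ROI x frame matrix.

    ``denoise=True`` applies a 3-frame median filter to the output, a
    light stand-in for model-based trace denoising (configurable off).
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    out = np.empty_like(traces)
    for i, row in enumerate(traces):
        out[i] = compute_dff(row, percentile, window_frames)
    if denoise:
        out = ndimage.median_filter(out, size=(1, 3), mode="nearest")
    return out


def skewness(x: np.ndarray) -> float:
    """Third central moment over the cubed standard deviation (1/N moments).

    Raises ``ValueError`` for zero-variance input.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std()  # population SD
    if sd == 0:
        raise ValueError("skewness undefined for zero-variance input")
    return float(np.mean((x - x.mean()) ** 3) / sd**3)


def _pearson_rows(rows: np.ndarray, regressor: np.ndarray) -> np.ndarray:
    """Pearson r of each row against a regressor; NaN for flat rows."""
    reg = regressor - regressor.mean()
    reg_ss = float(np.sqrt(np.sum(reg**2)))
    centered = rows - rows.mean(axis=1, keepdims=True)
    row_ss = np.sqrt(np.sum(centered**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = (centered @ reg) / (row_ss * reg_ss)
    cc[(row_ss == 0)] = np.nan
    if reg_ss == 0:
        cc[:] = np.nan
    return cc


def pixel_correlation_map(
    stack: ImageStack,
    regressor: np.ndarray,
    window_frames: int = DFF_WINDOW_FRAMES,
) -> np.ndarray:
    """Per-pixel Pearson correlation of ΔF/F with a frame-aligned regressor.

    Each pixel's raw time series is converted to ΔF/F (pixels with a
    non-positive percentile baseline are masked as NaN, as are
    zero-variance pixels), then correlated with ``regressor`` (length =
    number of frames).  Returns an H x W map in [-1, 1] with NaN where
    undefined.
    """
    regressor = np.asarray(regressor, dtype=float)
    T, H, W = stack.frames.shape
    if len(regressor) != T:
        raise ValueError("regressor length must equal the number of frames")
    flat = stack.frames.reshape(T, H * W).T  # pixels x T
    dff = np.full_like(flat, np.nan)
    for i, row in enumerate(flat):
        try:
            dff[i] = compute_dff(row, window_frames=window_frames)
        except ValueError:
            pass  # masked
    cc = _pearson_rows(np.nan_to_num(dff), regressor)
    cc[np.isnan(dff).all(axis=1)] = np.nan
    return cc.reshape(H, W)


def seed_correlation_map(
    stack: ImageStack,
    seed_trace: np.ndarray,
    window_frames: int = DFF_WINDOW_FRAMES,
    seed_is_dff: bool = False,
) -> np.ndarray:
    """Correlation map against a seed ROI's trace.

    ``seed_trace`` is the seed ROI's raw F (converted to ΔF/F here) or
    its ΔF/F if ``seed_is_dff``.
    """
    seed = np.asarray(seed_trace, dtype=float)
    if not seed_is_dff:
        seed = compute_dff(seed, window_frames=window_frames)
    return pixel_correlation_map(stack, seed, window_frames=window_frames)
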