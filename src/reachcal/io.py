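"""Readers and writers for the pipeline's on-disk formats.

Trial tables travel as CSV, cursor and ROI traces as HDF5 with sample
rates stored as dataset attributes, and image stacks as multi-page TIFF.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .core import CursorTrace, ImageStack, RoiTraceMatrix, ShiftSeries, validate_trial_table


def write_trial_table(trials: pd.DataFrame, path: str | Path) -> None:
    validate_trial_table(trials)
    trials.to_csv(path, index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    return validate_trial_table(trials)


def write_cursor_trace(trace: CursorTrace, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("cursor", data=trace.samples)
        d.attrs["rate"] = trace.rate
        d.attrs["t0"] = trace.t0
        d.attrs["units"] = "mm"


def read_cursor_trace(path: str | Path) -> CursorTrace:
    with h5py.File(path, "r") as f:
        d = f["cursor"]
        return CursorTrace(d[()], rate=float(d.attrs["rate"]), t0=float(d.attrs["t0"]))


def write_roi_traces(mat: RoiTraceMatrix, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("traces", data=mat.traces)
        d.attrs["rate"] = mat.rate
        d.attrs["t0"] = mat.t0
        d.attrs["kind"] = mat.kind
        if mat.centroids is not None:
            c = f.create_dataset("centroids", data=mat.centroids)
            c.attrs["units"] = "um"


def read_roi_traces(path: str | Path) -> RoiTraceMatrix:
    with h5py.File(path, "r") as f:
        d = f["traces"]
        centroids = f["centroids"][()] if "centroids" in f else None
        return RoiTraceMatrix(
            d[()],
            rate=float(d.attrs["rate"]),
            kind=str(d.attrs["kind"]),
            centroids=centroids,
            t0=float(d.attrs["t0"]),
        )


def write_shift_series(shifts: ShiftSeries, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("shifts", data=shifts.shifts)
        d.attrs["pixel_size"] = shifts.pixel_size


def read_shift_series(path: str | Path) -> ShiftSeries:
    with h5py.File(path, "r") as f:
        d = f["shifts"]
        return ShiftSeries(d[()], pixel_size=float(d.attrs["pixel_size"]))


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    tifffile.imwrite(
        path,
        stack.frames.astype(np.float32),
        metadata={"rate_hz": stack.rate, "pixel_size_um": stack.pixel_size},
    )


def read_image_stack(path: str | Path, rate: float = 30.0, pixel_size: float = 1.0) -> ImageStack:
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    rate = float(meta.get("rate_hz", rate))
    pixel_size = float(meta.get("pixel_size_um", pixel_size))
    return ImageStack(frames, rate=rate, pixel_size=pixel_size)
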