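#!/usr/bin/env python
"""Spatial correlation structure: pairwise activity vs distance and
pixel-wise correlation maps.

Computes, on the simulated reaching session, (a) Pearson correlations
of ΔF/F between ROI pairs during successful-trial onset windows against
centroid distance with the Spearman trend, and (b) pixel-wise
correlation maps of the image stack against the Y cursor trajectory and
against a seed ROI's trace.
"""

import json
from pathlib import Path

import numpy as np

from reachcal import imaging, io
from reachcal.neurostats import pairwise_corr_vs_distance

SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "sim_data"
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    RESULTS.mkdir(parents=True, exist_ok=True)
    trials = io.read_trial_table(SCRATCH / "reaching_trials.csv")
    raw = io.read_roi_traces(SCRATCH / "reaching_traces.h5")
    dff = raw.with_traces(imaging.compute_dff_matrix(raw.traces), "dFF")

    pairs, rho, p = pairwise_corr_vs_distance(dff, trials)
    pairs.to_csv(RESULTS / "pairwise_corr_distance.csv", index=False)

    stack = io.read_image_stack(SCRATCH / "reaching_stack.tif")
    cursor = io.read_cursor_trace(SCRATCH / "reaching_cursor.h5")
    # Y cursor trajectory downsampled to the frame clock
    idx = np.clip((np.arange(stack.n_frames) / stack.rate * cursor.rate).astype(int),
                  0, len(cursor) - 1)
    regressor = cursor.samples[idx, 1]
    cc_map = imaging.pixel_correlation_map(stack, regressor, window_frames=300)
    seed_map = imaging.seed_correlation_map(
        stack, stack.frames[:, 8, 8], window_frames=300)
    np.savetxt(SCRATCH / "cursor_correlation_map.csv", np.round(cc_map, 4), delimiter=",")

    summary = {
        "n_pairs": int(len(pairs)),
        "spearman_cc_vs_distance": rho,
        "spearman_p": p,
        "cursor_map_max_abs_cc": float(np.nanmax(np.abs(cc_map))),
        "seed_map_max_offseed_cc": float(np.nanmax(seed_map[16:, 16:])),
    }
    with open(RESULTS / "correlation_structure.json", "w") as f:
        json.dump(summary, f, indent=1, sort_keys=True)
    print(json.dumps(summary, indent=1, sort_keys=True))
    print(f"CC-vs-distance Spearman rho = {rho:.3f} (p = {p:.2g}). The default "
          "generator draws ROI event trains independently, so no distance "
          "trend is expected here beyond shared task locking; sensitivity to "
          "a planted distance-decaying common signal is exercised in the tests.")


if __name__ == "__main__":
    main()
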