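#!/usr/bin/env python
"""Direction selectivity of the simulated two-target session.

Runs the reaching pipeline end to end: ΔF/F, trial alignment, the
task-relevance rank-sum screen, per-ROI DSI, the 1000-shuffle null band
over DSI histogram bins, high-|DSI| fractions, and the recovered-sign
accuracy against the generator's ground truth.
"""

import json
from pathlib import Path

from reachcal import pipeline

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    summary = pipeline.run_reaching_analysis({
        "seed": 1,
        "out_dir": str(RESULTS / "reaching"),
        "simulate": {"n_trials": 120, "n_rois": 40},
        "analysis": {"n_shuffles_dsi": 1000},
    })
    show = {k: v for k, v in summary.items() if k != "provenance"}
    print(json.dumps(pipeline._round_floats(show), indent=1, sort_keys=True))
    print(f"{summary['n_task_relevant']}/{summary['n_rois']} ROIs task-relevant; "
          f"{summary['n_bins_above_band']} DSI bins exceed the shuffle band; "
          f"recovered DSI sign matches the planted tuning for "
          f"{summary['dsi_sign_accuracy']:.0%} of tuned ROIs.")


if __name__ == "__main__":
    main()
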