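#!/usr/bin/env python
"""Generate the synthetic study data every downstream analysis uses.

Writes a two-target reaching session and a force-field adaptation
session (trial tables, 1 kHz cursor traces, 30 Hz ROI fluorescence,
a small jittered image stack) under scratch/sim_data/, and a short
session inventory under results/.
"""

import json
from pathlib import Path

from reachcal import io, synth
from reachcal.forcefield import BlockSchedule

SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "sim_data"
RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    inventory = {}

    # two-target reaching session
    cfg = synth.SimConfig(n_trials=120, n_rois=40, seed=SEED)
    trials, cursor = synth.gen_reaching_session(cfg)
    truth = synth.gen_ground_truth(cfg)
    traces = synth.gen_calcium_traces(trials, truth, cfg)
    stack, true_shifts = synth.gen_image_stack(truth, traces, cfg, n_frames=400)
    io.write_trial_table(trials, SCRATCH / "reaching_trials.csv")
    io.write_cursor_trace(cursor, SCRATCH / "reaching_cursor.h5")
    io.write_roi_traces(traces, SCRATCH / "reaching_traces.h5")
    io.write_image_stack(stack, SCRATCH / "reaching_stack.tif")
    truth.to_csv(SCRATCH / "reaching_ground_truth.csv", index=False)
    inventory["reaching"] = {
        "n_trials": int(len(trials)),
        "n_success": int((trials["outcome"] == "success").sum()),
        "n_rois": int(traces.n_rois),
        "n_frames": int(traces.n_frames),
        "stack_frames": int(stack.n_frames),
    }
    print(f"reaching session: {inventory['reaching']}")

    # force-field adaptation session (baseline 40 / FF 20 / washout 40)
    acfg = synth.SimConfig(
        n_rois=40, seed=SEED + 1,
        block_effects={"ff_up": 0.2, "step_up": 0.1, "washout_up": 0.1, "none": 0.6},
    )
    schedule = BlockSchedule([("baseline", 40), ("FF", 20), ("washout", 40)])
    atrials, acursor, info = synth.gen_adaptation_session(acfg, schedule)
    atraces = synth.gen_calcium_traces(atrials, synth.gen_ground_truth(acfg), acfg)
    io.write_trial_table(atrials.drop(columns=["x_displacement"]), SCRATCH / "adaptation_trials.csv")
    atrials.to_csv(SCRATCH / "adaptation_trials_full.csv", index=False)
    io.write_cursor_trace(acursor, SCRATCH / "adaptation_cursor.h5")
    io.write_roi_traces(atraces, SCRATCH / "adaptation_traces.h5")
    inventory["adaptation"] = {
        "n_trials": int(len(atrials)),
        "blocks": atrials["block"].value_counts().to_dict(),
        "unmet_blocks": info["unmet_blocks"],
    }
    print(f"adaptation session: {inventory['adaptation']}")

    with open(RESULTS / "session_inventory.json", "w") as f:
        json.dump(inventory, f, indent=1, sort_keys=True)
    print(f"wrote {SCRATCH} and {RESULTS / 'session_inventory.json'}")


if __name__ == "__main__":
    main()
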