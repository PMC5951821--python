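import numpy as np
import pandas as pd
import pytest

from reachcal import imaging, neurostats, synth


@pytest.fixture(scope="session")
def tuned_session():
    """Medium two-target session with tuned ROIs, shared across tests."""
    sim = synth.SimConfig(n_trials=60, n_rois=30, seed=11)
    trials, cursor = synth.gen_reaching_session(sim)
    truth = synth.gen_ground_truth(sim)
    raw = synth.gen_calcium_traces(trials, truth, sim)
    dff = raw.with_traces(imaging.compute_dff_matrix(raw.traces), "dFF")
    return {"sim": sim, "trials": trials, "cursor": cursor, "truth": truth,
            "raw": raw, "dff": dff}


@pytest.fixture(scope="session")
def aligned(tuned_session):
    return neurostats.align_trials(
        tuned_session["dff"], tuned_session["trials"], cursor=tuned_session["cursor"]
    )


def make_block_trials(n_per_block=20, rng=None):
    """Minimal baseline/FF/washout trial table with evenly spaced onsets."""
    rng = rng or np.random.default_rng(0)
    rows = []
    t = 0.0
    for b in ("baseline", "FF", "washout"):
        for _ in range(n_per_block):
            rows.append({
                "trial_id": len(rows), "block": b, "target": 1, "outcome": "success",
                "t_fix_start": t, "t_reach_start": t + 0.8, "t_move_onset": t + 1.0,
                "t_end": t + 2.0,
            })
            t += 4.0
    return pd.DataFrame(rows)
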