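"""Force-field reach simulation with a trial-by-trial adaptive controller.

The task applies a curl-type perturbation during force-field (FF)
blocks: the lateral (x) force at millisecond ``t`` is

    F_x(t) = k_V * V_Y(t),   V_Y(t) = [Y(t) - Y(t-10)] / 10

with ``k_V`` in N·ms/mm and cursor positions in mm, so ``V_Y`` is in
mm/ms.  The y axis increases toward the animal (a pull is +y), which
makes the field push in +x during the reach.  No force is applied in
baseline and washout blocks.

The arm/cursor is modelled as a damped point mass driven by PD feedback
around a minimum-jerk reference plus a feedforward lateral compensation
proportional to an adaptation state (``feedforward_gain``).  The state
is updated after every trial by a linear state-space learning rule with
retention, producing the canonical adaptation signature: a large early
L-turn that partially decays over the FF block, an opposite-signed
aftereffect at washout start, and a return to baseline by washout end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BLOCK_LABELS, CursorTrace


@dataclass
class ForceFieldParams:
    """Velocity-dependent field: F_x = k_V * V_Y with a finite lag."""

    k_V: float = 20.0   # N·ms/mm
    lag: float = 10.0   # ms, finite-difference interval for V_Y
    on: bool = True

    def __post_init__(self) -> None:
        if self.k_V < 0:
            raise ValueError("k_V must be >= 0")
        if not self.lag > 0:
            raise ValueError("lag must be > 0")


@dataclass
class SpringParams:
    """Restoring spring toward a center: magnitude k * d."""

    k: float = 0.1      # N/mm
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")


@dataclass
class ControllerParams:
    """Point-mass plant with PD feedback and adaptive feedforward.

    Gains are tuned so an unperturbed reach is completed (target held)
    within roughly a second, and a naive (gain 0) force-field reach
    shows a lateral L-turn on the order of 10 mm, as in the task the
    simulator emulates.
    """

    mass: float = 0.1            # kg
    damping: float = 0.8         # N·ms/mm (viscous)
    kp: float = 0.11             # N/mm position feedback
    kd: float = 10.0             # N·ms/mm velocity feedback
    feedforward_gain: float = 0.0  # adaptation state in [0, 1]
    learning_rate: float = 0.06    # per trial
    retention: float = 0.90        # per trial
    expected_k_V: float = 20.0     # N·ms/mm used by the feedforward term
    error_scale: float = 13.0      # mm normalizing the trial error
    reach_duration: float = 400.0  # ms of the minimum-jerk reference
    motor_noise_sd: float = 0.12   # N, white force noise
    max_duration: float = 1400.0   # ms hard cap per trial
    hold_ms: float = 300.0         # required in-target hold
    success_deadline: float = 1000.0  # ms from onset to complete the hold
    x_bound: float = 15.0          # mm, trial terminated beyond this
    target_halfwidth: float = 8.0  # mm (x)
    target_halfheight: float = 4.0  # mm (y)

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError("mass must be > 0")
        if not 0.0 <= self.retention <= 1.0:
            raise ValueError("retention must be in [0, 1]")


@dataclass
class BlockSchedule:
    """Ordered blocks, each run until its success quota is met."""

    blocks: list[tuple[str, int]]

    def __post_init__(self) -> None:
        for label, n in self.blocks:
            if label not in BLOCK_LABELS:
                raise ValueError(f"unknown block label {label!r}; expected {BLOCK_LABELS}")
            if n <= 0:
                raise ValueError("success quota must be > 0")


def velocity_dependent_force(y_history: np.ndarray, t: int, params: ForceFieldParams) -> float:
    """Field force (N, +x) at millisecond ``t`` of a 1 kHz Y history.

    Returns ``k_V * [Y(t) - Y(t - lag)] / lag``; zero when the field is
    off.  If the history does not reach back ``lag`` ms, the force is
    zero by the start-of-trial convention (with a warning).
    """
    if not params.on:
        return 0.0
    lag = int(round(params.lag))
    if t < lag or t >= len(y_history):
        warnings.warn("insufficient history for V_Y; force set to 0")
        return 0.0
    v_y = (y_history[t] - y_history[t - lag]) / params.lag  # mm/ms
    return params.k_V * v_y


def spring_force(pos: np.ndarray, params: SpringParams) -> np.ndarray:
    """Restoring force vector (N) of magnitude k*d toward the center."""
    pos = np.asarray(pos, dtype=float)
    delta = np.asarray(params.center, dtype=float) - pos
    return params.k * delta


def minimum_jerk(start: np.ndarray, target: np.ndarray, duration: float, t: np.ndarray):
    """Minimum-jerk position and velocity at times ``t`` (ms).

    Past ``duration`` the reference holds at the target with zero
    velocity.
    """
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    s = np.clip(np.asarray(t, dtype=float) / duration, 0.0, 1.0)
    shape = 10 * s**3 - 15 * s**4 + 6 * s**5
    dshape = (30 * s**2 - 60 * s**3 + 30 * s**4) / duration  # per ms
    delta = target - start
    pos = start + shape[..., None] * delta
    vel = dshape[..., None] * delta
    return pos, vel


def update_adaptation(gain: float, error: float, ctrl: ControllerParams) -> float:
    """One step of the state-space learning rule, clipped to [0, 1].

    gain' = retention * gain + learning_rate * (error / error_scale)
    where ``error`` is the trial's signed x displacement (mm).
    """
    new = ctrl.retention * gain + ctrl.learning_rate * (error / ctrl.error_scale)
    return float(np.clip(new, 0.0, 1.0))


@dataclass
class TrialResult:
    trajectory: np.ndarray     # (N, 2) mm at 1 kHz, from movement onset
    outcome: str               # "success" | "fail"
    x_displacement: float      # signed, mm
    duration_ms: float


def simulate_trial(
    start,
    target,
    fieldp: ForceFieldParams,
    ctrl: ControllerParams,
    rng: np.random.Generator | None = None,
) -> TrialResult:
    """Integrate one reach at 1 kHz (explicit Euler).

    Success requires holding the cursor inside the target box for
    ``ctrl.hold_ms`` completed within ``ctrl.success_deadline`` ms after
    movement onset; exceeding ``ctrl.x_bound`` laterally terminates the
    trial as a failure.
    """
    rng = rng or np.random.default_rng()
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    n_max = int(ctrl.max_duration)
    lag = int(round(fieldp.lag))

    t_ms = np.arange(n_max, dtype=float)
    ref_pos, ref_vel = minimum_jerk(start, target, ctrl.reach_duration, t_ms)

    pos = start.copy()
    vel = np.zeros(2)
    traj = np.empty((n_max, 2))
    hold = 0
    outcome = "fail"
    end = n_max
    acc_scale = 1e-3 / ctrl.mass  # N -> mm/ms^2

    for t in range(n_max):
        traj[t] = pos
        # feedback + damping
        f = ctrl.kp * (ref_pos[t] - pos) + ctrl.kd * (ref_vel[t] - vel) - ctrl.damping * vel
        # adaptive feedforward opposing the anticipated field
        f[0] -= ctrl.feedforward_gain * ctrl.expected_k_V * ref_vel[t, 1]
        # the field itself, from the realized trajectory history
        if fieldp.on and fieldp.k_V > 0 and t >= lag:
            v_y = (traj[t, 1] - traj[t - lag, 1]) / fieldp.lag
            f[0] += fieldp.k_V * v_y
        if ctrl.motor_noise_sd > 0:
            f = f + rng.normal(0.0, ctrl.motor_noise_sd, size=2)
        vel = vel + f * acc_scale
        pos = pos + vel

        if abs(pos[0] - start[0]) > ctrl.x_bound:
            end = t + 1
            break
        in_target = (abs(pos[0] - target[0]) <= ctrl.target_halfwidth) and (
            abs(pos[1] - target[1]) <= ctrl.target_halfheight
        )
        hold = hold + 1 if in_target else 0
        if hold >= ctrl.hold_ms:
            if t <= ctrl.success_deadline:
                outcome = "success"
            end = t + 1
            break

    traj = traj[:end]
    dev = traj[:, 0] - start[0]
    xd = float(dev[np.argmax(np.abs(dev))]) if len(dev) else 0.0
    return TrialResult(trajectory=traj, outcome=outcome, x_displacement=xd, duration_ms=float(end))


def simulate_schedule(
    schedule: BlockSchedule,
    ctrl: ControllerParams,
    fieldp: ForceFieldParams,
    rng: np.random.Generator | None = None,
    start=(0.0, 0.0),
    target=(0.0, 20.0),
    max_trials_per_block: int = 200,
    fixation_duration: float = 0.8,
    iti_success: float = 1.5,
    iti_fail: float = 3.5,
    rate: float = 1000.0,
) -> tuple[pd.DataFrame, CursorTrace, dict]:
    """Run blocks to their success quotas with adaptation carried across.

    Returns a trial table, the concatenated 1 kHz cursor trace (cursor
    parked at the fixation point during fixation and inter-trial
    intervals), and an info dict with the per-trial feedforward gain and
    any blocks whose quota was not reached within the trial cap.
    """
    rng = rng or np.random.default_rng()
    start = np.asarray(start, dtype=float)
    gain = ctrl.feedforward_gain
    rows, chunks, gains = [], [], []
    unmet: list[str] = []
    t_cursor = 0.0
    trial_id = 0

    for label, quota in schedule.blocks:
        on = fieldp.on and label == "FF"
        block_field = ForceFieldParams(k_V=fieldp.k_V, lag=fieldp.lag, on=on)
        successes = 0
        n_in_block = 0
        while successes < quota and n_in_block < max_trials_per_block:
            trial_ctrl = ControllerParams(**{**ctrl.__dict__, "feedforward_gain": gain})
            res = simulate_trial(start, target, block_field, trial_ctrl, rng)

            n_fix = int(round(fixation_duration * rate))
            fix_chunk = np.tile(start, (n_fix, 1))
            t_fix_start = t_cursor
            t_reach_start = t_cursor + n_fix / rate
            t_move_onset = t_reach_start  # simulated movement starts at reach onset
            t_end = t_move_onset + len(res.trajectory) / rate

            iti = iti_success if res.outcome == "success" else iti_fail
            n_iti = int(round(iti * rate))
            iti_chunk = np.tile(start, (n_iti, 1))

            chunks.extend([fix_chunk, res.trajectory, iti_chunk])
            t_cursor = t_end + n_iti / rate

            rows.append(
                {
                    "trial_id": trial_id,
                    "block": label,
                    "target": 1,
                    "outcome": res.outcome,
                    "t_fix_start": t_fix_start,
                    "t_reach_start": t_reach_start,
                    "t_move_onset": t_move_onset,
                    "t_end": t_end,
                    "x_displacement": res.x_displacement,
                }
            )
            gains.append(gain)
            gain = update_adaptation(gain, res.x_displacement, ctrl)
            successes += res.outcome == "success"
            n_in_block += 1
            trial_id += 1
        if successes < quota:
            unmet.append(label)
            warnings.warn(f"block {label!r}: quota {quota} not met within {max_trials_per_block} trials")

    trials = pd.DataFrame(rows)
    trace = CursorTrace(np.concatenate(chunks) if chunks else np.empty((0, 2)), rate=rate)
    info = {"feedforward_gain": np.asarray(gains), "unmet_blocks": unmet}
    return trials, trace, info
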