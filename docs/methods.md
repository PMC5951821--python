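# Methods

This note documents the models and procedures implemented in
`reachcal`, the defaults and why they were chosen, what the synthetic
data do and do not emulate, and the numerical decisions a user should
know before trusting a number.

## Coordinate and timing conventions

Cursor/pole positions are in millimetres in the hand workspace
(53 × 90 mm bounds). The y axis increases toward the animal, so a pull
toward the near target has positive Y velocity; with the force law
F_x = k_V · V_Y this puts the field push in +x during the reach, and
"field-push-positive" lateral displacement needs no sign flip.
Behavior is sampled at 1 kHz and imaging at 30 Hz; the two clocks share
t = 0 with zero offset, and alignment between them is nearest-frame
lookup. All trial timestamps are seconds from session start.

## Synthetic sessions

The generator stands in for raw data that cannot be redistributed; its
defaults are the study conditions the analyses assume.

* **Reaching trials.** Fixation 0.8 s (cursor parked at the fixation
  center), a 0.15–0.35 s reaction lag, a minimum-jerk reach of 0.5 s
  (jittered ±15% per trial) to a target 20 mm above or below fixation,
  a 0.3 s hold, then an inter-trial interval of 1.5 s (success) or
  3.5 s (failure). Positional noise is white Gaussian smoothed with a
  40 ms kernel and rescaled to 0.2 mm SD — a tremor-band process;
  per-sample white noise at 1 kHz would dominate the path-length
  denominator of the straightness index, which no manipulandum
  recording does. A configurable fraction of trials (default 10%)
  overshoots through the target; outcome labels are then *derived* from
  the trajectory (did the cursor hold inside the target box?), so the
  labels are consistent with the kinematics by construction. With
  these defaults the generator produces session metrics in the
  trained-animal range (mean SI ≈ 0.92, RMSD_x ≈ 0.2 mm,
  RMSD_y ≈ 0.9 mm, ~85% success).
* **Calcium traces.** Per ROI, an inhomogeneous Poisson event train:
  baseline 0.1 events/s, multiplied by (1 + tuning_gain), default 9×,
  in a −1…+2 s window around movement onsets of the ROI's preferred
  target, and by a per-block multiplier for ROIs carrying a block
  pattern. Events (unit-mean exponential amplitudes) are convolved
  with a difference-of-exponentials kernel, rise 50 ms and decay
  600 ms — within the published GCaMP6f range; the source study states
  none — on a positive baseline with 5% slow multiplicative drift and
  white noise (0.05 ΔF/F SD). The baseline rate is deliberately sparse:
  at substantially higher background rates the fixation period fills
  with transients and the task-relevance contrast collapses, which is a
  property of the screen, not a bug.
* **Image stacks.** Frames are sums of 2-D Gaussian ROI footprints
  weighted by each frame's fluorescence on a flat background, rigidly
  shifted by a smooth AR(1) jitter (stationary SD = `jitter_sd` px,
  lag-1 correlation 0.95) with Poisson shot noise. True shifts are
  returned for oracle tests. The rendered field (64 px over 509 µm,
  ~8 µm/px) is far coarser than a real acquisition; shift SDs in µm are
  therefore not comparable to real-rig values and only the pixel-level
  contracts are meaningful.
* **Seeding.** One seed expands into named substreams (behavior,
  truth, events, noise, jitter) via `SeedSequence.spawn`, so identical
  configs are bit-identical and each component can be regenerated
  independently.

What the generator does **not** emulate: photon/PMT physics, neuropil
contamination, non-rigid tissue deformation, distance-dependent shared
variability between ROIs (event trains are independent; spatial
correlation structure is exercised in tests with planted common
signals), eye or licking behavior, and satiation/motivation dynamics.
Passing recovery tests therefore demonstrates that the statistics
recover what the forward model plants — not that they are robust to
every failure mode of real tissue.

## Force-field simulation

The arm/cursor is a point mass (0.1 kg) with viscous damping
(0.8 N·ms/mm), PD feedback (kp = 0.11 N/mm, kd = 10 N·ms/mm) around a
minimum-jerk reference (400 ms), integrated by explicit Euler at 1 kHz
(matching the 1 kHz analog sampling of the task). The field force
follows the finite-difference law exactly (F_x = k_V·[Y(t)−Y(t−10)]/10,
k_V = 20 N·ms/mm, zero for the first 10 ms of a trial where no history
exists). Success requires a 300 ms in-target hold completed within 1 s
of movement onset; the trial aborts as a failure if |x| exceeds 15 mm.
Trial-by-trial adaptation is a linear state-space rule,
gain ← retention·gain + learning_rate·(x-displacement/13 mm), clipped
to [0, 1], with the gain driving an anticipatory lateral force
−gain·k_V·V_Y^ref.

The free parameters were calibrated once against the qualitative
adaptation pattern the task is known to produce, then frozen: the
unperturbed reach is straight (SI > 0.99) and completes in ~0.6 s; a
naive field trial shows a ~13.5 mm L-turn (just inside the 15 mm
abort); learning_rate = 0.06 and retention = 0.90 leave adaptation
deliberately incomplete (late-FF displacement ≈ 0.65 of the first
trial — the displacement does not return to zero within a 20-trial FF
block) while letting the aftereffect wash out fully within a 40-trial
washout block (end-of-washout mean within ~0.02 mm of baseline,
against single-trial noise of ~0.16 mm). A higher retention meets the
FF-decay target but strands a residual aftereffect at washout end,
contradicting the second behavior; both constraints together pin the
pair. Motor noise (0.12 N white force noise) sets the baseline
lateral-displacement SD to ~0.2 mm.

## ΔF/F and motion correction

* **Baseline.** F0(t) is the running 8th percentile of raw F over a
  centered 900-frame window (±15 s at 30 Hz). Traces are first
  extended by 450 frames on each side with the first/last value, so
  every output frame has a full window — no shrinking edge windows.
  Percentiles use linear interpolation between order statistics; the
  8th percentile of a 900-sample window is method-sensitive, so the
  choice is part of the contract and the test oracle recomputes it
  independently (manual sort + interpolation).
* **Denoising.** Model-based source extraction is out of scope; the
  optional "denoised" ΔF/F is a 3-frame median filter on the ΔF/F
  output, a deliberately light stand-in that is off by default in the
  low-level API and on in the pipeline runners.
* **Motion correction.** Rigid shifts are estimated from the Fourier
  cross-power spectrum with 20× upsampled sub-pixel refinement
  (scikit-image's phase correlation), each frame translated back by
  its negated shift with frame-median edge fill. Registration against
  the stack mean recovers planted shifts only up to the jitter path's
  mean — a constant offset shared by all frames — so recovery accuracy
  is assessed on mean-centered shift series (residual ~0.07 px RMS at
  default SNR). Flat (zero-variance) images yield (0, 0) with a
  warning rather than an error.
* **Skewness.** Population moments (1/N), m₃/σ³; undefined (error) at
  zero variance. The >0.5 screening threshold for active ROIs is the
  conventional one for transient-dominated traces.

## Trial-aligned statistics

* **Alignment.** Onset-window means use frames with onset-relative
  time in [−1 s, +2 s] inclusive; fixation baselines average fixation-
  period frames, restricted to frames where the cursor sits within
  4 mm of the fixation center when a cursor trace is available.
  Trials whose window extends beyond the recording are excluded with a
  warning (the first trial of a session typically loses its −1 s
  pre-window). Successful trials only, by default.
* **Task relevance.** One-sided Wilcoxon rank-sum per ROI at
  P < 0.05, uncorrected across ROIs (each ROI is reported
  individually; no family-wise claim is made).
* **DSI.** Negative window means are floored at 0 before the ratio,
  keeping DSI in [−1, 1] and matching its "active only during"
  reading; ROIs with R1 + R2 ≤ 0 are excluded as undefined. Histogram
  bins are 0.25 wide over [−1, 1].
* **Permutation scheme.** All shuffle nulls permute labels across
  trials *jointly* for every ROI (one permutation per shuffle),
  preserving the cross-ROI correlation structure of the session; this
  is the exchangeability the bands assume. Bands are 95th percentiles
  of the per-shuffle statistic; on discrete statistics (fractions of a
  small ROI count) the strict-exceedance test is conservative.
* **Block classification.** Kruskal-Wallis omnibus at P < 0.05, then
  pairwise two-sided rank-sum contrasts at the Dunn-Sidak level
  1 − 0.95^{1/3} ≈ 0.0170. The rank-sum statistic is used for the
  pairwise step (the post-hoc statistic is a design choice here); the
  seven groups are the seven non-empty significance patterns over
  (baseline-FF, FF-washout, baseline-washout), an all-non-significant
  triple maps to no group.
* **ROI matching.** Across sessions, the global field shift is
  estimated by registering time-averaged images, applied to centroids,
  then greedy mutual-nearest matching with a 5 µm cutoff. DSI
  stability is the Spearman correlation of matched-ROI DSIs, split at
  a 5-day session interval; classes with fewer than three pairs are
  reported undefined.

## Problem sizes and calibration checks

The test suite validates the 5% type-I calibration of the relevance
test and the omnibus classification on 1000 exchangeable replicates,
and the shuffle bands on 50 (DSI) / 25 (groups) null populations at
100 shuffles each; band-exceedance rates are checked against an upper
bound only, because strict exceedance of a discrete 95th-percentile
band is conservative. Parameter recovery uses 200 ROIs at high SNR
(DSI sign ≥ 95%) and 10-SD block effects at 20 trials/block (pattern
recovery ≥ 90%). Adaptation signatures are checked over 100 seeded
baseline-10/FF-20/washout-40 runs with one-sided sign tests at
P < 0.01. The ΔF/F oracle covers 100 random 5000-frame traces, exact
to floating point. These sizes keep the full suite at a few minutes on
one core while leaving every Monte-Carlo band with comfortable margin.

## Known limitations

The controller is the simplest plant that reproduces the L-turn;
it makes no biomechanical claims, and its aftereffect magnitude
(relative to the L-turn) is larger than real limbs show because all
compensation is modelled as anticipatory force rather than partly as
impedance. Pixel-level ΔF/F maps use the same running-percentile
baseline as ROI traces, which is noisy for dim pixels (masked where
the baseline is non-positive). The CNMF-style noise-level metric
(high-frequency SD per pixel) is not implemented: its defining cutoff
is not specifiable from the available description, and guessing one
would produce numbers that look comparable but are not.
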