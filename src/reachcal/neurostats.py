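"""Trial-aligned neural statistics: task relevance, direction
selectivity, block classification and their permutation nulls.

Definitions implemented here:

* Task-relevant ROI: mean ΔF/F in the −1..+2 s window around movement
  onset of successful trials significantly exceeds the fixation-period
  mean (one-sided Wilcoxon rank-sum, P < 0.05 per ROI, uncorrected).
* DSI = (R1 − R2) / (R1 + R2) with R1/R2 the trial-averaged onset-window
  means for reaches to targets 1/2 (negative means floored at 0); +1
  means the ROI responded only to target 1.
* DSI shuffle null: target labels permuted across trials (jointly over
  ROIs), DSI recomputed per shuffle, and per histogram bin the 95th
  percentile of the per-shuffle bin fractions.
* Block classification: Kruskal-Wallis across the baseline/FF/washout
  per-trial means; if P < 0.05, pairwise rank-sum contrasts at the
  Dunn-Sidak level 1 − (1 − 0.05)^(1/3) assign one of seven
  significance patterns.
* Group-fraction null: block labels permuted across successful trials
  (jointly over ROIs), classification re-run, 95th percentile of each
  group's fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import CursorTrace, RoiTraceMatrix

#: Canonical order of the three adaptation blocks.
BLOCK_ORDER = ("baseline", "FF", "washout")

#: The three pairwise contrasts, in reporting order.
PAIRS = (("baseline", "FF"), ("FF", "washout"), ("baseline", "washout"))

#: The seven assignable significance patterns (any pattern with at least
#: one significant pairwise contrast); an all-nonsignificant triple maps
#: to ``None``.
GROUP_PATTERNS = tuple(
    p for p in ((a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)) if any(p)
)

SIDAK_ALPHA = 1.0 - (1.0 - 0.05) ** (1.0 / 3.0)


def pattern_name(pattern: tuple[int, int, int] | None) -> str:
    if pattern is None:
        return "none"
    return "".join(str(int(b)) for b in pattern)


@dataclass
class AlignedResponses:
    """Per-ROI, per-trial window means used by every downstream test.

    ``onset_means``/``fix_means`` are ROI x trial arrays of mean ΔF/F in
    the onset window and the fixation period; ``trials`` carries the
    per-trial metadata (target, block, outcome) in the same column
    order.
    """

    onset_means: np.ndarray
    fix_means: np.ndarray
    trials: pd.DataFrame
    window: tuple[float, float] = (-1.0, 2.0)

    @property
    def n_rois(self) -> int:
        return self.onset_means.shape[0]

    @property
    def n_trials(self) -> int:
        return self.onset_means.shape[1]

    def select(self, mask: np.ndarray) -> "AlignedResponses":
        return AlignedResponses(
            self.onset_means[:, mask],
            self.fix_means[:, mask],
            self.trials.loc[mask].reset_index(drop=True),
            self.window,
        )


def align_trials(
    traces: RoiTraceMatrix,
    trials: pd.DataFrame,
    window: tuple[float, float] = (-1.0, 2.0),
    cursor: CursorTrace | None = None,
    fixation_radius: float = 4.0,
    successful_only: bool = True,
) -> AlignedResponses:
    """Mean ΔF/F per ROI per trial in the onset window and fixation period.

    The onset window selects frames with onset-relative time in
    ``[window[0], window[1]]`` (inclusive); the fixation baseline
    averages frames of the fixation period, restricted (when a cursor
    trace is supplied) to frames where the cursor sits within
    ``fixation_radius`` mm of the fixation center.  Trials whose window
    extends beyond the trace are excluded with a warning.
    """
    if traces.kind == "raw_F":
        raise ValueError("align_trials expects ΔF/F traces; run compute_dff first")
    use = trials
    if successful_only:
        use = trials[trials["outcome"] == "success"]
    rate = traces.rate
    times = traces.frame_times

    kept, onset_rows, fix_rows = [], [], []
    n_dropped = 0
    for _, tr in use.iterrows():
        onset = tr["t_move_onset"]
        sel = (times >= onset + window[0]) & (times <= onset + window[1])
        if onset + window[0] < times[0] - 0.5 / rate or onset + window[1] > times[-1] + 0.5 / rate:
            n_dropped += 1
            continue
        fix_sel = (times >= tr["t_fix_start"]) & (times < tr["t_reach_start"])
        if cursor is not None:
            fr_t = times[fix_sel]
            idx = np.clip(((fr_t - cursor.t0) * cursor.rate).round().astype(int), 0, len(cursor) - 1)
            inside = np.linalg.norm(cursor.samples[idx], axis=1) <= fixation_radius
            fix_idx = np.flatnonzero(fix_sel)[inside]
        else:
            fix_idx = np.flatnonzero(fix_sel)
        if not sel.any() or fix_idx.size == 0:
            n_dropped += 1
            continue
        onset_rows.append(traces.traces[:, sel].mean(axis=1))
        fix_rows.append(traces.traces[:, fix_idx].mean(axis=1))
        kept.append(tr)
    if n_dropped:
        warnings.warn(f"{n_dropped} trial(s) excluded from alignment (truncated window)")
    if not kept:
        return AlignedResponses(
            np.empty((traces.n_rois, 0)), np.empty((traces.n_rois, 0)),
            use.iloc[0:0].reset_index(drop=True), window,
        )
    return AlignedResponses(
        np.column_stack(onset_rows),
        np.column_stack(fix_rows),
        pd.DataFrame(kept).reset_index(drop=True),
        window,
    )


def task_relevance_test(resp: AlignedResponses, alpha: float = 0.05) -> pd.DataFrame:
    """One-sided rank-sum of onset-window vs fixation means per ROI.

    Returns a frame with ``roi``, ``p`` and ``task_relevant``
    (p < alpha).  ROIs with fewer than two trials in either sample are
    flagged not relevant with p = NaN.
    """
    n = resp.n_trials
    rows = []
    for r in range(resp.n_rois):
        if n < 2:
            rows.append((r, np.nan, False))
            continue
        x, y = resp.onset_means[r], resp.fix_means[r]
        if np.ptp(np.concatenate([x, y])) == 0:
            rows.append((r, 1.0, False))  # zero-variance equal samples
            continue
        p = stats.mannwhitneyu(x, y, alternative="greater").pvalue
        rows.append((r, float(p), bool(p < alpha)))
    return pd.DataFrame(rows, columns=["roi", "p", "task_relevant"])


def dsi(r1: float, r2: float) -> float:
    """Direction selectivity index (R1 − R2)/(R1 + R2) in [−1, 1].

    Negative inputs are floored at zero first; raises ``ValueError``
    when R1 + R2 <= 0 after flooring (the ROI carries no onset-window
    response and is excluded upstream).
    """
    r1, r2 = max(float(r1), 0.0), max(float(r2), 0.0)
    if r1 + r2 <= 0:
        raise ValueError("DSI undefined: R1 + R2 <= 0")
    return (r1 - r2) / (r1 + r2)


def _dsi_vector(onset_means: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Vectorized per-ROI DSI; NaN where undefined or a target is absent."""
    m1, m2 = targets == 1, targets == 2
    if m1.sum() == 0 or m2.sum() == 0:
        return np.full(onset_means.shape[0], np.nan)
    r1 = np.maximum(onset_means[:, m1].mean(axis=1), 0.0)
    r2 = np.maximum(onset_means[:, m2].mean(axis=1), 0.0)
    tot = r1 + r2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (r1 - r2) / tot
    out[tot <= 0] = np.nan
    return out


def dsi_table(resp: AlignedResponses, relevance: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-ROI R1, R2 and DSI (successful trials assumed upstream)."""
    targets = resp.trials["target"].to_numpy()
    m1, m2 = targets == 1, targets == 2
    r1 = np.maximum(resp.onset_means[:, m1].mean(axis=1), 0.0) if m1.any() else np.full(resp.n_rois, np.nan)
    r2 = np.maximum(resp.onset_means[:, m2].mean(axis=1), 0.0) if m2.any() else np.full(resp.n_rois, np.nan)
    vals = _dsi_vector(resp.onset_means, targets)
    out = pd.DataFrame({"roi": np.arange(resp.n_rois), "R1": r1, "R2": r2, "dsi": vals})
    if relevance is not None:
        out = out.merge(relevance[["roi", "p", "task_relevant"]], on="roi")
    return out


@dataclass
class NullBand:
    """Per-bin (or per-group) shuffle statistics."""

    labels: np.ndarray        # bin edges or group names
    observed: np.ndarray
    shuffle_mean: np.ndarray
    percentile95: np.ndarray
    n_shuffles: int


def dsi_histogram(values: np.ndarray, bin_width: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Fractions of defined DSI values per bin over [−1, 1]."""
    edges = np.round(np.arange(-1.0, 1.0 + bin_width / 2, bin_width), 10)
    vals = values[np.isfinite(values)]
    counts, _ = np.histogram(vals, bins=edges)
    frac = counts / max(len(vals), 1)
    return edges, frac


def dsi_shuffle_null(
    resp: AlignedResponses,
    n_shuffles: int = 1000,
    bin_width: float = 0.25,
    rng: np.random.Generator | None = None,
) -> NullBand:
    """Trial-shuffle null band for the DSI histogram.

    Target labels are permuted across trials (the same permutation for
    every ROI, preserving cross-ROI structure), the per-ROI DSI is
    recomputed and binned, and each bin's shuffle-mean fraction and the
    95th percentile of its per-shuffle fractions are reported alongside
    the observed fractions.
    """
    rng = rng or np.random.default_rng()
    targets = resp.trials["target"].to_numpy()
    if (targets == 1).sum() < 2 or (targets == 2).sum() < 2:
        raise ValueError("need at least two trials per target")
    edges, observed = dsi_histogram(_dsi_vector(resp.onset_means, targets), bin_width)
    fracs = np.empty((n_shuffles, len(edges) - 1))
    for s in range(n_shuffles):
        perm = rng.permutation(len(targets))
        _, fracs[s] = dsi_histogram(_dsi_vector(resp.onset_means, targets[perm]), bin_width)
    return NullBand(
        labels=edges,
        observed=observed,
        shuffle_mean=fracs.mean(axis=0),
        percentile95=np.percentile(fracs, 95, axis=0),
        n_shuffles=n_shuffles,
    )


def high_dsi_fractions(dsis: np.ndarray) -> tuple[float, float]:
    """Fractions of ROIs with DSI > 0.5 and DSI < −0.5 (strict)."""
    vals = np.asarray(dsis, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no defined DSI values")
    return float(np.mean(vals > 0.5)), float(np.mean(vals < -0.5))


def classify_blocks(
    block_means: dict[str, np.ndarray],
    omnibus_alpha: float = 0.05,
    posthoc_alpha: float = SIDAK_ALPHA,
) -> dict:
    """Kruskal-Wallis omnibus + Dunn-Sidak pairwise classification.

    ``block_means`` maps each of baseline/FF/washout to that block's
    per-trial onset-window means for one ROI.  Returns a dict with
    ``omnibus_p``, the pairwise significance triple (baseline-FF,
    FF-washout, baseline-washout) and ``group`` (one of the seven
    patterns, or ``None`` when the omnibus test fails or no contrast is
    significant).
    """
    groups = [np.asarray(block_means[b], dtype=float) for b in BLOCK_ORDER]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each block needs at least two trials")
    if np.ptp(np.concatenate(groups)) == 0:
        return {"omnibus_p": 1.0, "pairwise": (0, 0, 0), "group": None}
    omnibus_p = float(stats.kruskal(*groups).pvalue)
    if not omnibus_p < omnibus_alpha:
        return {"omnibus_p": omnibus_p, "pairwise": (0, 0, 0), "group": None}
    triple = []
    data = dict(zip(BLOCK_ORDER, groups))
    for a, b in PAIRS:
        p = stats.mannwhitneyu(data[a], data[b], alternative="two-sided").pvalue
        triple.append(int(p < posthoc_alpha))
    triple = tuple(triple)
    return {"omnibus_p": omnibus_p, "pairwise": triple, "group": triple if any(triple) else None}


def classify_blocks_table(resp: AlignedResponses) -> pd.DataFrame:
    """Per-ROI block classification from aligned responses."""
    blocks = resp.trials["block"].to_numpy()
    rows = []
    for r in range(resp.n_rois):
        bm = {b: resp.onset_means[r, blocks == b] for b in BLOCK_ORDER}
        try:
            res = classify_blocks(bm)
            rows.append(
                {
                    "roi": r,
                    "omnibus_p": res["omnibus_p"],
                    "sig_baseline_FF": res["pairwise"][0],
                    "sig_FF_washout": res["pairwise"][1],
                    "sig_baseline_washout": res["pairwise"][2],
                    "group": pattern_name(res["group"]),
                }
            )
        except ValueError:
            rows.append({"roi": r, "omnibus_p": np.nan, "sig_baseline_FF": 0,
                         "sig_FF_washout": 0, "sig_baseline_washout": 0, "group": "unclassifiable"})
    return pd.DataFrame(rows)


def group_fractions(classification: pd.DataFrame) -> dict[str, float]:
    """Fraction of ROIs per seven-group pattern (and 'none')."""
    usable = classification[classification["group"] != "unclassifiable"]
    n = max(len(usable), 1)
    out = {pattern_name(p): 0.0 for p in GROUP_PATTERNS}
    out["none"] = 0.0
    for g, cnt in usable["group"].value_counts().items():
        out[g] = cnt / n
    return out


def group_fraction_null(
    resp: AlignedResponses,
    n_shuffles: int = 10000,
    rng: np.random.Generator | None = None,
) -> NullBand:
    """Shuffle null for the seven group fractions.

    Block labels are permuted across (successful) trials — one shared
    permutation per shuffle for all ROIs — the classification re-run,
    and each group's 95th-percentile shuffle fraction reported.
    """
    rng = rng or np.random.default_rng()
    blocks = resp.trials["block"].to_numpy()
    names = [pattern_name(p) for p in GROUP_PATTERNS] + ["none"]
    obs = group_fractions(classify_blocks_table(resp))
    fracs = np.empty((n_shuffles, len(names)))
    shuffled = AlignedResponses(resp.onset_means, resp.fix_means, resp.trials.copy(), resp.window)
    for s in range(n_shuffles):
        perm = rng.permutation(len(blocks))
        shuffled.trials["block"] = blocks[perm]
        gf = group_fractions(classify_blocks_table(shuffled))
        fracs[s] = [gf[n] for n in names]
    return NullBand(
        labels=np.asarray(names, dtype=object),
        observed=np.asarray([obs[n] for n in names]),
        shuffle_mean=fracs.mean(axis=0),
        percentile95=np.percentile(fracs, 95, axis=0),
        n_shuffles=n_shuffles,
    )


def pairwise_corr_vs_distance(
    traces: RoiTraceMatrix,
    trials: pd.DataFrame,
    condition: str = "success",
    window: tuple[float, float] = (-1.0, 2.0),
) -> tuple[pd.DataFrame, float, float]:
    """Pairwise activity correlation against inter-ROI distance.

    Concatenates each ROI's ΔF/F over the onset windows of trials with
    the selected outcome, computes Pearson correlations for every ROI
    pair and pairs them with Euclidean centroid distances (µm).
    Returns (pair table, Spearman rho of CC vs distance, p-value).
    Zero-variance ROIs are skipped.
    """
    if traces.centroids is None:
        raise ValueError("traces must carry centroids")
    if traces.n_rois < 2:
        raise ValueError("need at least two ROIs")
    sel = trials[trials["outcome"] == condition]
    times = traces.frame_times
    mask = np.zeros(traces.n_frames, dtype=bool)
    for onset in sel["t_move_onset"]:
        mask |= (times >= onset + window[0]) & (times <= onset + window[1])
    segs = traces.traces[:, mask]
    keep = segs.std(axis=1) > 0
    cc = np.corrcoef(segs[keep])
    cents = traces.centroids[keep]
    idx = np.flatnonzero(keep)
    rows = []
    for a, b in combinations(range(keep.sum()), 2):
        dist = float(np.linalg.norm(cents[a] - cents[b]))
        rows.append({"roi_a": int(idx[a]), "roi_b": int(idx[b]), "distance_um": dist, "cc": float(cc[a, b])})
    pairs = pd.DataFrame(rows)
    if len(pairs) < 3:
        return pairs, np.nan, np.nan
    rho, p = stats.spearmanr(pairs["distance_um"], pairs["cc"])
    return pairs, float(rho), float(p)


def match_rois_across_sessions(
    centroids_a: np.ndarray,
    centroids_b: np.ndarray,
    mean_image_a: np.ndarray | None = None,
    mean_image_b: np.ndarray | None = None,
    pixel_size: float = 1.0,
    cutoff_um: float = 5.0,
) -> pd.DataFrame:
    """Match ROIs between two sessions of the same field.

    When mean images are given, the global field shift is estimated by
    rigid registration and removed from session b's centroids; matching
    is then greedy mutual-nearest-centroid with a distance cutoff.
    Returns a table of (roi_a, roi_b, distance_um); unmatched ROIs are
    simply absent.
    """
    from .imaging import estimate_rigid_shift

    a = np.asarray(centroids_a, dtype=float)
    b = np.asarray(centroids_b, dtype=float).copy()
    if mean_image_a is not None and mean_image_b is not None:
        dx, dy = estimate_rigid_shift(mean_image_b, mean_image_a)
        b[:, 0] -= dx * pixel_size
        b[:, 1] -= dy * pixel_size
    if len(a) == 0 or len(b) == 0:
        return pd.DataFrame(columns=["roi_a", "roi_b", "distance_um"])
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    rows = []
    used_a, used_b = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for ia, ib in order:
        if d[ia, ib] > cutoff_um:
            break
        if ia in used_a or ib in used_b:
            continue
        # mutual nearest among unused
        rows.append({"roi_a": int(ia), "roi_b": int(ib), "distance_um": float(d[ia, ib])})
        used_a.add(ia)
        used_b.add(ib)
    return pd.DataFrame(rows, columns=["roi_a", "roi_b", "distance_um"])


def dsi_stability(
    pairs: pd.DataFrame,
    interval_split_days: float = 5.0,
) -> dict[str, dict]:
    """Spearman correlation of matched-ROI DSIs by session interval.

    ``pairs`` needs columns ``day_i``, ``day_j``, ``dsi_i``, ``dsi_j``;
    pairs with ``day_j - day_i <= interval_split_days`` form the "short"
    class, the rest the "long" class.  Classes with fewer than three
    pairs are reported as undefined (NaN) with a flag.
    """
    intervals = pairs["day_j"] - pairs["day_i"]
    out = {}
    for name, mask in (("short", intervals <= interval_split_days), ("long", intervals > interval_split_days)):
        sub = pairs[mask]
        if len(sub) < 3:
            out[name] = {"rho": np.nan, "p": np.nan, "n": int(len(sub)), "defined": False}
            continue
        rho, p = stats.spearmanr(sub["dsi_i"], sub["dsi_j"])
        out[name] = {"rho": float(rho), "p": float(p), "n": int(len(sub)), "defined": True}
    return out
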