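"""Behavioral event extraction and burst--behavior analyses.

Reach/grasp onsets come from the hand-speed profile: smooth the position
trace with an 11-frame Gaussian kernel (SD 1 frame), find the frame where
the hand crosses the apparatus line, take the peak speed in a +/-200 ms
window around that frame, then walk backwards (forwards) from the peak to
the first frame with speed below 0.1 x peak to get reach (grasp) start.
Missing position samples propagate as NaN and are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal.windows import gaussian as gaussian_window


@dataclass
class TrialKinematicEvents:
    trial: int
    crossing_time: float  # NaN if the hand never crosses the line
    peak_speed: float
    reach_start: float  # NaN if undefined
    grasp_start: float  # NaN if undefined

    @property
    def valid(self) -> bool:
        return np.isfinite(self.reach_start) and np.isfinite(self.grasp_start)


def smooth_positions(position: np.ndarray, n_taps: int = 11, sd: float = 1.0):
    """NaN-aware Gaussian smoothing along axis 0."""
    w = gaussian_window(n_taps, sd)
    position = np.asarray(position, dtype=float)
    out = np.full_like(position, np.nan)
    half = n_taps // 2
    n = position.shape[0]
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        seg = position[lo:hi]
        ww = w[lo - (i - half) : hi - (i - half)]
        for d in range(position.shape[1]):
            vals = seg[:, d]
            ok = np.isfinite(vals)
            if ok.any():
                out[i, d] = np.sum(vals[ok] * ww[ok]) / np.sum(ww[ok])
    return out


def hand_speed(position: np.ndarray, frame_times: np.ndarray) -> np.ndarray:
    """Per-frame speed of the (smoothed) position trace.

    Central differences keep each speed sample centered on its frame (the
    end frames fall back to one-sided differences), so threshold crossings
    land on the correct frame.
    """
    position = np.asarray(position, dtype=float)
    n = len(frame_times)
    speed = np.full(n, np.nan)
    if n < 2:
        return speed
    disp = np.linalg.norm(position[2:] - position[:-2], axis=1)
    speed[1:-1] = disp / (frame_times[2:] - frame_times[:-2])
    speed[0] = np.linalg.norm(position[1] - position[0]) / (frame_times[1] - frame_times[0])
    speed[-1] = np.linalg.norm(position[-1] - position[-2]) / (
        frame_times[-1] - frame_times[-2]
    )
    return speed


def detect_reach_grasp_events(
    position: np.ndarray,
    frame_times: np.ndarray,
    crossing_x: float,
    trial: int = 0,
    window_s: float = 0.2,
    peak_frac: float = 0.1,
    smooth: bool = True,
) -> TrialKinematicEvents:
    """Extract reach/grasp start for one trial's frames (door open to end)."""
    frame_times = np.asarray(frame_times, dtype=float)
    pos = smooth_positions(position) if smooth else np.asarray(position, float)
    speed = hand_speed(pos, frame_times)
    x = pos[:, 0]
    crossed = np.flatnonzero(np.isfinite(x) & (x >= crossing_x))
    nan = float("nan")
    if crossed.size == 0:
        return TrialKinematicEvents(trial, nan, nan, nan, nan)
    cross = int(crossed[0])
    frame_rate = 1.0 / float(np.median(np.diff(frame_times)))
    half = int(round(window_s * frame_rate))
    lo = max(0, cross - half)
    hi = min(len(speed), cross + half + 1)
    seg = speed[lo:hi]
    if not np.isfinite(seg).any():
        return TrialKinematicEvents(trial, frame_times[cross], nan, nan, nan)
    peak_rel = int(np.nanargmax(seg))
    peak = lo + peak_rel
    peak_speed = float(speed[peak])
    level = peak_frac * peak_speed
    reach_start = nan
    for i in range(peak, -1, -1):
        if np.isfinite(speed[i]) and speed[i] < level:
            reach_start = float(frame_times[i])
            break
    grasp_start = nan
    for i in range(peak, len(speed)):
        if np.isfinite(speed[i]) and speed[i] < level:
            grasp_start = float(frame_times[i])
            break
    return TrialKinematicEvents(
        trial, float(frame_times[cross]), peak_speed, reach_start, grasp_start
    )


# ---------------------------------------------------------------------------
# Behavioral metrics
# ---------------------------------------------------------------------------


def normalized_duration(duration: float, slot: str, prestroke_means: dict) -> float:
    """Duration over the pre-stroke mean duration for the same slot."""
    if slot not in prestroke_means:
        raise KeyError(f"slot {slot!r} missing from pre-stroke table")
    mean = prestroke_means[slot]
    if mean <= 0:
        raise ValueError(f"pre-stroke mean for slot {slot!r} must be > 0")
    return float(duration) / float(mean)


def trial_times(
    trials: pd.DataFrame,
    timeout: float = 10.0,
) -> pd.Series:
    """Per-trial total time: reach start to reward if rewarded, else timeout.

    ``trials`` needs columns trial, rewarded, reach_start, reward_time.
    """
    out = {}
    for _, row in trials.iterrows():
        if row["rewarded"] and np.isfinite(row.get("reward_time", np.nan)):
            out[row["trial"]] = row["reward_time"] - row["reach_start"]
        else:
            out[row["trial"]] = timeout
    return pd.Series(out, name="trial_time")


def recovery_index(
    daily_trials: dict,
    prestroke_means: dict,
    timeout: float = 10.0,
    early_late_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-day recovery table.

    ``daily_trials`` maps day id -> trial DataFrame (columns trial, slot,
    rewarded, reach_start, reward_time), ordered by day; the first entry is
    the first post-stroke day. Per trial: total time (timeout-capped),
    normalised by the pre-stroke mean trial time of its slot; day mean is
    decremented by 1, divided by the first day's value, and subtracted
    from 1, so day 1 scores 0 and pre-stroke parity scores 1.
    """
    days = list(daily_trials)
    if not days:
        raise ValueError("need at least one post-stroke day")
    day_means = {}
    pct_correct = {}
    for day in days:
        tdf = daily_trials[day]
        tt = trial_times(tdf, timeout)
        norm = np.array(
            [
                normalized_duration(tt[row["trial"]], row["slot"], prestroke_means)
                for _, row in tdf.iterrows()
            ]
        )
        day_means[day] = float(norm.mean())
        pct_correct[day] = float(tdf["rewarded"].mean())
    first = day_means[days[0]] - 1.0
    if first <= 0:
        raise ValueError(
            "first post-stroke day shows no deficit; recovery index undefined"
        )
    rows = []
    for day in days:
        idx = 1.0 - (day_means[day] - 1.0) / first
        rows.append(
            {
                "day": day,
                "mean_normalized_trial_time": day_means[day],
                "percent_correct": pct_correct[day],
                "recovery_index": idx,
                "phase": "early" if idx < early_late_threshold else "late",
            }
        )
    return pd.DataFrame(rows)


def define_epochs(
    trials: pd.DataFrame, timeout: float = 10.0
) -> tuple[dict, dict]:
    """Reach ([reach start, grasp start)) and grasp epochs per trial.

    Grasp epoch ends at the reward for rewarded trials and at door open +
    ``timeout`` otherwise. Trials missing the needed events are omitted.
    """
    reach, grasp = {}, {}
    for _, row in trials.iterrows():
        rs = row.get("reach_start", np.nan)
        gs = row.get("grasp_start", np.nan)
        if np.isfinite(rs) and np.isfinite(gs):
            reach[row["trial"]] = (float(rs), float(gs))
        if not np.isfinite(gs):
            continue
        if row.get("rewarded", False) and np.isfinite(row.get("reward_time", np.nan)):
            end = float(row["reward_time"])
        elif np.isfinite(row.get("door_open", np.nan)):
            end = float(row["door_open"]) + timeout
        else:
            continue
        if end > gs:
            grasp[row["trial"]] = (float(gs), end)
    return reach, grasp


# ---------------------------------------------------------------------------
# Burst--behavior analyses
# ---------------------------------------------------------------------------


def align_burst_fraction(
    events: list,
    align_times: pd.Series,
    window: float = 0.35,
) -> float:
    """Fraction of trials with >= 1 event overlapping [t - window, t + window].

    A trial counts once regardless of how many events fall in its window.
    """
    times = align_times.dropna()
    if len(times) == 0:
        return float("nan")
    hits = 0
    for t in times:
        lo, hi = t - window, t + window
        if any(ev.start < hi and ev.end > lo for ev in events):
            hits += 1
    return hits / len(times)


def burst_occupancy_vs_trial_time(
    events: list,
    trials: pd.DataFrame,
    prestroke_trial_means: dict | None = None,
) -> pd.DataFrame:
    """Per-trial burst occupancy of [reach start, last lift) vs. trial length.

    Occupancy is total in-category event time inside the interval divided by
    the interval length. Trial length is the interval length, normalised by
    the pre-stroke per-slot mean when a table is given.
    """
    rows = []
    for _, row in trials.iterrows():
        rs, ll = row.get("reach_start", np.nan), row.get("last_lift", np.nan)
        if not (np.isfinite(rs) and np.isfinite(ll)) or ll <= rs:
            continue
        length = ll - rs
        covered = 0.0
        for ev in events:
            covered += max(0.0, min(ev.end, ll) - max(ev.start, rs))
        norm_len = length
        if prestroke_trial_means is not None:
            norm_len = length / prestroke_trial_means[row["slot"]]
        rows.append(
            {
                "trial": row["trial"],
                "occupancy": covered / length,
                "trial_length": length,
                "normalized_trial_length": norm_len,
            }
        )
    return pd.DataFrame(rows, columns=["trial", "occupancy", "trial_length",
                                       "normalized_trial_length"])


def speed_by_burst_category(
    speed: np.ndarray,
    frame_times: np.ndarray,
    labels: np.ndarray,
    fs: float,
    epochs: list[tuple[float, float]],
) -> dict:
    """Per-frame category assignment and per-category speed samples.

    Frames are matched to label samples by nearest time; frames outside all
    epochs are excluded. Returns {category: speed-sample array}.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    in_epoch = np.zeros(len(frame_times), dtype=bool)
    for t0, t1 in epochs:
        in_epoch |= (frame_times >= t0) & (frame_times < t1)
    idx = np.clip(np.round(frame_times * fs).astype(int), 0, len(labels) - 1)
    frame_labels = labels[idx]
    out = {}
    for code, name in ((0, "none"), (1, "local"), (2, "global")):
        sel = in_epoch & (frame_labels == code) & np.isfinite(speed)
        out[name] = np.asarray(speed)[sel]
    return out
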