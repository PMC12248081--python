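"""Spatial clustering of bursting channels on the electrode grid.

The per-event statistic is the activity-weighted mean distance of channels
to the activity-weighted burst center. The null is built by concatenating
every event's binary channel x time array along time, permuting whole
columns (each column keeps its channel set), re-cutting at the original
event lengths, and recomputing the statistic -- repeated ``n_shuffles``
times. This conserves the column multiset exactly, hence both the average
number of channels per burst and each channel's total activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from betaburst.burst_classify import PopulationBurstEvent


@dataclass
class BurstSpatialSummary:
    loccenter: np.ndarray  # (n_events, 2) mm
    distcenter: np.ndarray  # (n_events,) mm
    shuffle_mean: float  # mm, mean of the null distribution
    centered_dist: np.ndarray  # distcenter - shuffle_mean
    null_distances: np.ndarray  # all null distcenter values
    session: str = ""
    epoch_class: str = ""

    @property
    def mean(self) -> float:
        return float(self.centered_dist.mean())

    @property
    def se(self) -> float:
        n = len(self.centered_dist)
        return float(self.centered_dist.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")

    @property
    def frac_below_zero(self) -> float:
        return float((self.centered_dist < 0).mean())


def burst_center_and_distance(
    fracact: np.ndarray, geometry: np.ndarray
) -> tuple[np.ndarray, float]:
    """Weighted burst center and weighted mean distance to it.

    center   = sum_c fracact_c * loc_c / sum_c fracact_c
    distance = sum_c fracact_c * ||loc_c - center|| / sum_c fracact_c
    """
    fracact = np.asarray(fracact, dtype=float)
    geometry = np.asarray(geometry, dtype=float)
    total = fracact.sum()
    if total <= 0:
        raise ValueError("all fracact values are zero")
    center = (fracact[:, None] * geometry).sum(axis=0) / total
    dists = np.linalg.norm(geometry - center[None, :], axis=1)
    return center, float((fracact * dists).sum() / total)


def event_distances(
    events: list[PopulationBurstEvent], geometry: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    centers = np.empty((len(events), 2))
    dists = np.empty(len(events))
    for i, ev in enumerate(events):
        centers[i], dists[i] = burst_center_and_distance(ev.fracact, geometry)
    return centers, dists


def _concatenate_masks(
    events: list[PopulationBurstEvent], channel_masks: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    blocks = [channel_masks[:, ev.start_idx : ev.stop_idx] for ev in events]
    lengths = np.array([b.shape[1] for b in blocks])
    return np.concatenate(blocks, axis=1), lengths


def shuffle_null_distances(
    events: list[PopulationBurstEvent],
    channel_masks: np.ndarray,
    geometry: np.ndarray,
    n_shuffles: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Null distcenter distribution from the column-shuffle procedure."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if len(events) == 0:
        raise ValueError("need at least one event")
    big, lengths = _concatenate_masks(events, channel_masks)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    rng = np.random.default_rng(seed)
    n_cols = big.shape[1]
    null: list[float] = []
    for _ in range(n_shuffles):
        perm = rng.permutation(n_cols)
        shuffled = big[:, perm]
        for i in range(len(lengths)):
            seg = shuffled[:, offsets[i] : offsets[i + 1]]
            fracact = seg.mean(axis=1)
            if fracact.sum() <= 0:
                continue  # a resegmented event can be empty in principle
            _, d = burst_center_and_distance(fracact, geometry)
            null.append(d)
    null_arr = np.asarray(null)
    return null_arr, float(null_arr.mean())


def clustering_statistic(
    events: list[PopulationBurstEvent],
    channel_masks: np.ndarray,
    geometry: np.ndarray,
    n_shuffles: int = 100,
    seed: int = 0,
    session: str = "",
    epoch_class: str = "",
) -> BurstSpatialSummary:
    """True distcenter values centered by the shuffle-null mean."""
    centers, dists = event_distances(events, geometry)
    null, null_mean = shuffle_null_distances(
        events, channel_masks, geometry, n_shuffles=n_shuffles, seed=seed
    )
    return BurstSpatialSummary(
        loccenter=centers,
        distcenter=dists,
        shuffle_mean=null_mean,
        centered_dist=dists - null_mean,
        null_distances=null,
        session=session,
        epoch_class=epoch_class,
    )


def summary_to_frame(summary: BurstSpatialSummary, categories=None):
    import pandas as pd

    n = len(summary.distcenter)
    return pd.DataFrame(
        {
            "session": summary.session,
            "class": categories if categories is not None else summary.epoch_class,
            "event_id": np.arange(n),
            "x_center_mm": summary.loccenter[:, 0],
            "y_center_mm": summary.loccenter[:, 1],
            "distcenter_mm": summary.distcenter,
            "centered_dist_mm": summary.centered_dist,
        }
    )
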