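"""Local/global labelling of cortical burst timepoints.

Every sample is labelled 0 (non-bursting), 1 (local) or 2 (global):
label 2 iff the fraction of cortical channels bursting exceeds the
mixture-derived threshold; label 1 iff the fraction is at or below the
threshold and at least ``min_channels`` (3) channels are bursting; else 0.
Population events are maximal constant-label runs of 1s or 2s lasting at
least 100 ms.

The threshold is the crossing point of a two-component Gaussian mixture
fitted to the day-averaged distribution of the bursting fraction at
cortical-burst timepoints. Because an off-the-shelf mixture fit does not
take per-day weights, the EM here runs on a binned version of the averaged
distribution (each day's histogram normalised to unit mass before
averaging), which is the direct binned equivalent of fitting the averaged
density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class FractionSeries:
    """Per-sample bursting-channel count and fraction over included channels."""

    count: np.ndarray  # (n_samp,) int
    fraction: np.ndarray  # (n_samp,) in [0, 1]
    n_included: int


@dataclass
class LocalGlobalThreshold:
    threshold: float  # frac_thresh_global_local
    weights: np.ndarray  # (2,)
    means: np.ndarray  # (2,) sorted ascending
    sds: np.ndarray  # (2,)
    collapsed: bool = False  # True if the mixture degenerated (midpoint fallback)
    n_days: int = 0


@dataclass
class PopulationBurstEvent:
    """A contiguous cortical burst epoch labelled local or global."""

    category: str  # "local" | "global"
    start: float  # s
    end: float  # s
    start_idx: int
    stop_idx: int
    fracact: np.ndarray  # (n_ch,) fraction of event samples each channel bursts

    @property
    def duration(self) -> float:
        return self.end - self.start


def fraction_bursting(
    channel_masks: np.ndarray, included: np.ndarray | None = None
) -> FractionSeries:
    """Fraction of included cortical channels bursting at each sample."""
    channel_masks = np.atleast_2d(channel_masks)
    if included is not None:
        channel_masks = channel_masks[np.asarray(included, dtype=bool)]
    n_inc = channel_masks.shape[0]
    if n_inc == 0:
        raise ValueError("zero included channels")
    count = channel_masks.sum(axis=0).astype(int)
    return FractionSeries(count=count, fraction=count / n_inc, n_included=n_inc)


# ---------------------------------------------------------------------------
# Mixture threshold
# ---------------------------------------------------------------------------

_N_BINS = 200


def _average_histogram(per_day_samples: list[np.ndarray], n_bins: int = _N_BINS):
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hists = []
    for day in per_day_samples:
        day = np.asarray(day, dtype=float)
        h, _ = np.histogram(day, bins=edges)
        total = h.sum()
        if total == 0:
            raise ValueError("a day contributed no fraction samples")
        hists.append(h / total)
    return centers, np.mean(hists, axis=0)


def _weighted_gmm_1d(
    x: np.ndarray,
    w: np.ndarray,
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
):
    """EM for a 2-component 1-D Gaussian mixture on weighted points."""
    rng = np.random.default_rng(seed)
    w = w / w.sum()
    best = None
    best_ll = -np.inf
    mean0 = float(np.sum(w * x))
    sd0 = float(np.sqrt(np.sum(w * (x - mean0) ** 2)))
    for _ in range(n_restarts):
        mu = np.sort(rng.uniform(x.min(), x.max(), 2))
        sd = np.full(2, max(sd0, 1e-3))
        pi = np.array([0.5, 0.5])
        ll_prev = -np.inf
        for _ in range(max_iter):
            # E step
            log_pdf = (
                -0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
                - np.log(sd[None, :])
                - 0.5 * np.log(2 * np.pi)
                + np.log(pi[None, :])
            )
            m = log_pdf.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(log_pdf - m).sum(axis=1))
            resp = np.exp(log_pdf - lse[:, None])
            ll = float(np.sum(w * lse))
            # M step with point weights
            wk = w[:, None] * resp
            nk = wk.sum(axis=0)
            nk = np.maximum(nk, 1e-12)
            pi = nk / nk.sum()
            mu = (wk * x[:, None]).sum(axis=0) / nk
            var = (wk * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
            # SD floor of half a bin width guards against delta components
            sd = np.sqrt(np.maximum(var, 2.5e-5))
            if abs(ll - ll_prev) < tol:
                break
            ll_prev = ll
        if ll > best_ll:
            best_ll = ll
            best = (pi.copy(), mu.copy(), sd.copy())
    pi, mu, sd = best
    order = np.argsort(mu)
    return pi[order], mu[order], sd[order]


def _gaussian_crossing(w1, m1, s1, w2, m2, s2) -> float | None:
    """Root of w1*N(x; m1, s1) = w2*N(x; m2, s2) strictly between the means."""
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = (
        m2**2 / (2 * s2**2)
        - m1**2 / (2 * s1**2)
        + np.log((w1 * s2) / (w2 * s1))
    )
    lo, hi = sorted((m1, m2))
    if abs(a) < 1e-14:
        if abs(b) < 1e-14:
            return None
        root = -c / b
        return float(root) if lo < root < hi else None
    disc = b**2 - 4 * a * c
    if disc < 0:
        return None
    roots = [(-b + s * np.sqrt(disc)) / (2 * a) for s in (+1, -1)]
    inside = [r for r in roots if lo < r < hi]
    return float(inside[0]) if inside else None


def fit_local_global_threshold(
    per_day_fractions: list[np.ndarray],
    seed: int = 0,
    n_bins: int = _N_BINS,
) -> LocalGlobalThreshold:
    """Fit the two-Gaussian mixture and locate the between-means crossing.

    ``per_day_fractions``: one array per day of the bursting fraction at
    timepoints where at least ``min_channels`` channels burst. Per-day
    distributions are normalised to unit mass and averaged before fitting,
    so each day contributes equally.
    """
    if len(per_day_fractions) == 0:
        raise ValueError("need at least one day of fraction samples")
    if len(per_day_fractions) == 1:
        warnings.warn("fitting the local/global threshold from a single day")
    centers, avg = _average_histogram(per_day_fractions, n_bins)
    keep = avg > 0
    pi, mu, sd = _weighted_gmm_1d(centers[keep], avg[keep], seed=seed)
    collapsed = abs(mu[1] - mu[0]) < (sd[0] + sd[1]) / 10.0
    if collapsed:
        warnings.warn("mixture components collapsed; using midpoint fallback")
        thr = float(mu.mean())
    else:
        thr = _gaussian_crossing(pi[0], mu[0], sd[0], pi[1], mu[1], sd[1])
        if thr is None:
            # no crossing between the means (extreme weight imbalance)
            warnings.warn("no mixture crossing between means; using midpoint")
            thr = float(mu.mean())
            collapsed = True
    return LocalGlobalThreshold(
        threshold=thr,
        weights=pi,
        means=mu,
        sds=sd,
        collapsed=collapsed,
        n_days=len(per_day_fractions),
    )


# ---------------------------------------------------------------------------
# Labelling and event segmentation
# ---------------------------------------------------------------------------


def label_timepoints(
    fractions: FractionSeries, threshold: float, min_channels: int = 3
) -> np.ndarray:
    """Per-sample labels 0 (none) / 1 (local) / 2 (global)."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    labels = np.zeros(len(fractions.fraction), dtype=np.int8)
    # fewer than min_channels bursting is never a cortical burst timepoint
    enough = fractions.count >= min_channels
    is_global = enough & (fractions.fraction > threshold)
    is_local = enough & (fractions.fraction <= threshold)
    labels[is_global] = 2
    labels[is_local] = 1
    return labels


def segment_population_events(
    labels: np.ndarray,
    channel_masks: np.ndarray,
    fs: float,
    min_duration: float = 0.100,
) -> list[PopulationBurstEvent]:
    """Maximal constant-label runs of 1s or 2s, at least ``min_duration`` long.

    A direct local-to-global transition breaks both runs (runs must be
    label-pure). ``fracact`` per channel is the fraction of the event's
    samples during which that channel is itself bursting.
    """
    labels = np.asarray(labels)
    events: list[PopulationBurstEvent] = []
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], boundaries])
    stops = np.concatenate([boundaries, [len(labels)]])
    for start, stop in zip(starts, stops):
        lab = int(labels[start])
        if lab == 0:
            continue
        if (stop - start) / fs < min_duration - 1e-12:
            continue
        fracact = channel_masks[:, start:stop].mean(axis=1)
        events.append(
            PopulationBurstEvent(
                category="global" if lab == 2 else "local",
                start=start / fs,
                end=stop / fs,
                start_idx=int(start),
                stop_idx=int(stop),
                fracact=fracact,
            )
        )
    return events


def label_and_segment(
    fractions: FractionSeries,
    threshold: float,
    channel_masks: np.ndarray,
    fs: float,
    min_channels: int = 3,
    min_duration: float = 0.100,
) -> tuple[np.ndarray, list[PopulationBurstEvent]]:
    labels = label_timepoints(fractions, threshold, min_channels)
    return labels, segment_population_events(labels, channel_masks, fs, min_duration)


def subcortical_cooccurrence(
    events: list[PopulationBurstEvent], subcortical_masks: np.ndarray
) -> dict:
    """Fraction of in-event samples with >= 1 subcortical channel bursting."""
    subcortical_masks = np.atleast_2d(subcortical_masks)
    if subcortical_masks.shape[0] == 0:
        raise ValueError("no subcortical channels")
    any_sub = subcortical_masks.any(axis=0)
    out = {}
    for cat in ("local", "global"):
        n_in, n_co = 0, 0
        for ev in events:
            if ev.category != cat:
                continue
            n_in += ev.stop_idx - ev.start_idx
            n_co += int(any_sub[ev.start_idx : ev.stop_idx].sum())
        out[cat] = n_co / n_in if n_in else float("nan")
    return out


def events_to_frame(events: list[PopulationBurstEvent], session: str = ""):
    import pandas as pd

    return pd.DataFrame(
        {
            "session": session,
            "category": [e.category for e in events],
            "start_s": [e.start for e in events],
            "end_s": [e.end for e in events],
            "duration_s": [e.duration for e in events],
        }
    )
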