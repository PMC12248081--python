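"""Per-channel beta-burst detection with the dual-threshold rule.

A burst is a maximal run of envelope samples strictly above the per-channel
median that (a) lasts at least 100 ms and (b) contains at least one sample
at or above median + SD. The SD is the population SD (divisor n). Runs are
never merged across sub-threshold gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ChannelThresholds:
    """Per-channel session statistics of the beta envelope."""

    sigma: np.ndarray  # envelope SD per channel
    thresh: np.ndarray  # envelope median per channel
    thresh2: np.ndarray  # median + SD per channel

    def for_channel(self, ch: int) -> tuple[float, float, float]:
        return float(self.sigma[ch]), float(self.thresh[ch]), float(self.thresh2[ch])


@dataclass
class ChannelBurstEvent:
    """One supra-threshold envelope epoch on one channel."""

    channel: int
    start: float  # s
    end: float  # s  (half-open [start, end))
    start_idx: int
    stop_idx: int
    norm_amplitude: float  # (mean envelope - thresh) / sigma; NaN if sigma == 0
    duration: float  # s
    mean_frequency: float  # Hz


def compute_channel_thresholds(
    envelope: np.ndarray, sample_mask: np.ndarray | None = None
) -> ChannelThresholds:
    """Median, population SD and their sum, per channel.

    ``sample_mask`` restricts the statistics to artifact-free samples (e.g.
    concatenated trial windows); it applies to every channel.
    """
    envelope = np.atleast_2d(envelope)
    if sample_mask is not None:
        envelope = envelope[:, np.asarray(sample_mask, dtype=bool)]
    if envelope.shape[1] < 2:
        raise ValueError("need at least 2 samples per channel")
    if np.isnan(envelope).all(axis=1).any():
        raise ValueError("all-NaN channel in envelope")
    thresh = np.nanmedian(envelope, axis=1)
    sigma = np.nanstd(envelope, axis=1)  # population SD (ddof=0)
    return ChannelThresholds(sigma=sigma, thresh=thresh, thresh2=thresh + sigma)


def _runs_above(x: np.ndarray, level: float) -> list[tuple[int, int]]:
    """Half-open index spans of maximal runs where ``x > level``."""
    above = x > level
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        stops = np.concatenate([stops, [len(x)]])
    return list(zip(starts.tolist(), stops.tolist()))


def detect_channel_bursts(
    envelope: np.ndarray,
    thresholds: ChannelThresholds,
    fs: float,
    phase: np.ndarray | None = None,
    min_duration: float = 0.100,
) -> list[ChannelBurstEvent]:
    """Detect burst events on every channel of an (n_ch, n_samp) envelope.

    With ``phase`` given, mean frequency is filled in from the instantaneous
    frequency; otherwise it is NaN.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    envelope = np.atleast_2d(envelope)
    dphase = None
    if phase is not None:
        dphase = np.diff(np.unwrap(np.atleast_2d(phase), axis=1), axis=1)
    events: list[ChannelBurstEvent] = []
    for ch in range(envelope.shape[0]):
        sigma, thresh, thresh2 = thresholds.for_channel(ch)
        env = envelope[ch]
        for start, stop in _runs_above(env, thresh):
            duration = (stop - start) / fs
            # "at least 100 ms": ties at exactly 100 ms are kept
            if duration < min_duration - 1e-12:
                continue
            if env[start:stop].max() < thresh2:
                continue
            events.append(
                _make_event(ch, start, stop, env, dphase, sigma, thresh, fs)
            )
    return events


def _make_event(ch, start, stop, env, dphase, sigma, thresh, fs) -> ChannelBurstEvent:
    mean_amp = float(env[start:stop].mean())
    norm_amp = (mean_amp - thresh) / sigma if sigma > 0 else float("nan")
    if dphase is not None and stop - start >= 2:
        mean_freq = float(dphase[ch, start : stop - 1].mean() * fs / (2.0 * np.pi))
    else:
        mean_freq = float("nan")
    return ChannelBurstEvent(
        channel=ch,
        start=start / fs,
        end=stop / fs,
        start_idx=int(start),
        stop_idx=int(stop),
        norm_amplitude=norm_amp,
        duration=(stop - start) / fs,
        mean_frequency=mean_freq,
    )


def compute_burst_features(
    span: tuple[int, int],
    envelope: np.ndarray,
    phase: np.ndarray,
    thresholds: ChannelThresholds,
    fs: float,
    channel: int = 0,
) -> ChannelBurstEvent:
    """Features for one known span (half-open sample indices) on one channel."""
    start, stop = span
    envelope = np.atleast_2d(envelope)
    phase = np.atleast_2d(phase)
    if not (0 <= start < stop <= envelope.shape[1]):
        raise ValueError(f"invalid span {span}")
    sigma, thresh, _ = thresholds.for_channel(channel)
    dphase = np.diff(np.unwrap(phase, axis=1), axis=1)
    return _make_event(channel, start, stop, envelope[channel], dphase, sigma, thresh, fs)


def burst_masks(
    events: list[ChannelBurstEvent], n_channels: int, n_samples: int
) -> np.ndarray:
    """Boolean (n_ch, n_samp) array marking in-burst samples."""
    masks = np.zeros((n_channels, n_samples), dtype=bool)
    for ev in events:
        masks[ev.channel, ev.start_idx : ev.stop_idx] = True
    return masks


def events_to_frame(events: list[ChannelBurstEvent], session: str = ""):
    """Burst table with one row per event (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "session": session,
            "channel": [e.channel for e in events],
            "start_s": [e.start for e in events],
            "end_s": [e.end for e in events],
            "duration_s": [e.duration for e in events],
            "norm_amplitude": [e.norm_amplitude for e in events],
            "mean_freq_hz": [e.mean_frequency for e in events],
        }
    )
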