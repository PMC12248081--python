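"""LFP preprocessing: decimation, trial segmentation, PSDs, analytic beta signal.

Band-pass filtering is zero-phase (forward-backward Butterworth), so the
envelope of a symmetric transient stays aligned with its center; the
effective filter order is doubled relative to ``filter_order``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass
class AnalyticBetaSeries:
    """Band-limited analytic amplitude and phase, per channel per sample."""

    amplitude: np.ndarray  # (n_ch, n_samp), >= 0
    phase: np.ndarray  # (n_ch, n_samp), radians in (-pi, pi]
    fs: float
    band: tuple[float, float]
    filter_order: int
    edge_guard: float = 0.5  # s at either session end flagged unusable

    @property
    def n_samples(self) -> int:
        return self.amplitude.shape[1]

    def valid_mask(self) -> np.ndarray:
        """Samples clear of session-edge transform artifacts."""
        n_guard = int(round(self.edge_guard * self.fs))
        mask = np.ones(self.n_samples, dtype=bool)
        if n_guard > 0:
            mask[:n_guard] = False
            mask[-n_guard:] = False
        return mask

    def instantaneous_frequency(self) -> np.ndarray:
        """Per-sample frequency in Hz from the differentiated unwrapped phase.

        Returns an (n_ch, n_samp - 1) array: element ``t`` is the frequency
        between samples ``t`` and ``t + 1``.
        """
        dphase = np.diff(np.unwrap(self.phase, axis=1), axis=1)
        return dphase * self.fs / (2.0 * np.pi)


@dataclass
class TrialSegmentSet:
    """Per-trial sample windows relative to an alignment event."""

    alignment: str
    window: tuple[float, float]  # (pre, post) s, pre typically negative
    trial_ids: np.ndarray
    starts: np.ndarray  # sample index of window start per trial
    stops: np.ndarray  # sample index of window stop (exclusive)
    clipped: np.ndarray  # True where the window hit a session bound
    fs: float


def decimate_lfp(
    raw: np.ndarray, fs_raw: float, factor: int
) -> tuple[np.ndarray, float]:
    """Anti-aliased decimation of a (n_ch, n_samp) array.

    Returns the decimated signal (length ``ceil(n / factor)``) and the new
    sampling rate ``fs_raw / factor``.
    """
    raw = np.atleast_2d(raw)
    if factor < 1 or int(factor) != factor:
        raise ValueError("decimation factor must be a positive integer")
    if factor >= raw.shape[1]:
        raise ValueError("decimation factor must be smaller than the signal length")
    if factor == 1:
        return raw.copy(), float(fs_raw)
    out = signal.decimate(raw, int(factor), axis=1, zero_phase=True)
    return out, float(fs_raw) / factor


def segment_trials(
    event_times: np.ndarray,
    trial_ids: np.ndarray,
    window: tuple[float, float],
    fs: float,
    n_samples: int,
) -> TrialSegmentSet:
    """Half-open sample windows ``[t + pre, t + post)`` around each event.

    Windows reaching past the session bounds are clipped and flagged rather
    than silently shortened.
    """
    event_times = np.asarray(event_times, dtype=float)
    pre, post = window
    starts = np.round((event_times + pre) * fs).astype(int)
    stops = np.round((event_times + post) * fs).astype(int)
    clipped = (starts < 0) | (stops > n_samples)
    return TrialSegmentSet(
        alignment="event",
        window=(pre, post),
        trial_ids=np.asarray(trial_ids),
        starts=np.clip(starts, 0, n_samples),
        stops=np.clip(stops, 0, n_samples),
        clipped=clipped,
        fs=fs,
    )


def compute_psd(
    lfp: np.ndarray,
    segments: TrialSegmentSet,
    window_s: float = 4.0,
    overlap_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD averaged over channels and trial segments.

    Uses ``window_s``-second windows with ``overlap_s`` seconds of overlap.
    """
    fs = segments.fs
    nperseg = int(round(window_s * fs))
    noverlap = int(round(overlap_s * fs))
    freqs = None
    acc = None
    count = 0
    for start, stop in zip(segments.starts, segments.stops):
        if stop - start < nperseg:
            continue
        f, p = signal.welch(
            lfp[:, start:stop], fs=fs, nperseg=nperseg, noverlap=noverlap, axis=1
        )
        freqs = f
        acc = p.mean(axis=0) if acc is None else acc + p.mean(axis=0)
        count += 1
    if count == 0:
        raise ValueError(
            f"no segment reaches the {window_s} s PSD window at fs={fs:g}"
        )
    return freqs, acc / count


def analytic_beta(
    lfp: np.ndarray,
    band: tuple[float, float],
    fs: float,
    order: int = 3,
) -> AnalyticBetaSeries:
    """Butterworth band-pass (zero-phase) then Hilbert analytic signal.

    The transform runs on the full session so that later trial windows carry
    no edge artifacts; the first/last 0.5 s are flagged via ``valid_mask``.
    """
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band {band} outside (0, Nyquist={fs / 2:g})")
    from scipy.fft import next_fast_len

    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, lfp, axis=1)
    n = filtered.shape[1]
    # zero-pad to a fast FFT length; the padding artifact is confined to the
    # session edges, which valid_mask already flags
    analytic = signal.hilbert(filtered, N=next_fast_len(n), axis=1)[:, :n]
    return AnalyticBetaSeries(
        amplitude=np.abs(analytic),
        phase=np.angle(analytic),
        fs=fs,
        band=(float(lo), float(hi)),
        filter_order=order,
    )


def exclude_noisy_channels(
    amplitude: np.ndarray,
    manual: tuple = (),
    auto_k: float | None = None,
) -> np.ndarray:
    """Boolean keep-mask over channels.

    ``manual`` lists channel indices to drop; with ``auto_k`` set, channels
    whose envelope SD exceeds ``auto_k`` times the median channel SD are also
    dropped (reproducible stand-in for manual artifact curation).
    """
    n_ch = amplitude.shape[0]
    keep = np.ones(n_ch, dtype=bool)
    for ch in manual:
        keep[ch] = False
    if auto_k is not None:
        sds = amplitude.std(axis=1)
        keep &= sds <= auto_k * np.median(sds)
    if not keep.any():
        raise ValueError("all channels excluded")
    return keep
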