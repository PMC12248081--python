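"""Unit-level analyses: inclusion metrics, firing statistics by burst
condition, spike--phase entrainment with a shuffle null, entrainment--rate
association, and one-step linear population-dynamics predictability.

Conventions pinned here:

- "firing rate variability" is the SD of the 10 ms-binned rate within an
  epoch (computed per trial, then trial-averaged);
- shuffle draws for the entrainment null are with replacement from the
  pooled in-burst phase samples of the channel;
- a 50 ms (or 10 ms) bin is assigned the majority label of the LFP samples
  it covers, ties going to the lower code (0 < 1 < 2);
- the per-trial R^2 uses one-step-ahead predictions seeded by the true
  previous bin (teacher forcing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


# ---------------------------------------------------------------------------
# Unit inclusion
# ---------------------------------------------------------------------------


@dataclass
class UnitRecord:
    unit: str
    spike_times: np.ndarray
    snr: float
    mean_rate: float  # Hz over the whole session
    included: bool


def unit_snr(
    mean_waveform: np.ndarray, exclusion: tuple[int, int]
) -> float:
    """Peak-minus-trough of the mean waveform over the SD of its samples
    outside the ``exclusion`` index window (half-open)."""
    wf = np.asarray(mean_waveform, dtype=float)
    if wf.size < 3:
        raise ValueError("waveform must have at least 3 samples")
    lo, hi = exclusion
    tail = np.concatenate([wf[:lo], wf[hi:]])
    if tail.size == 0:
        raise ValueError("exclusion window covers the whole waveform")
    peak_trough = wf.max() - wf.min()
    if peak_trough == 0:
        return 0.0
    sd = tail.std()
    return float(peak_trough / sd) if sd > 0 else float("inf")


def make_unit_records(
    spikes: dict,
    waveforms: dict,
    session_duration: float,
    exclusion_frac: tuple[float, float] = (0.3, 0.7),
    snr_min: float = 3.0,
    rate_min: float = 0.5,
) -> list[UnitRecord]:
    """Inclusion rule: SNR > 3 and mean session rate > 0.5 Hz."""
    records = []
    for unit in sorted(spikes):
        times = np.asarray(spikes[unit], dtype=float)
        wf_mean, _ = waveforms[unit]
        n = len(wf_mean)
        excl = (int(exclusion_frac[0] * n), int(exclusion_frac[1] * n))
        snr = unit_snr(wf_mean, excl)
        rate = len(times) / session_duration
        records.append(
            UnitRecord(
                unit=str(unit),
                spike_times=times,
                snr=snr,
                mean_rate=rate,
                included=(snr > snr_min and rate > rate_min),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Epoch firing statistics
# ---------------------------------------------------------------------------


@dataclass
class EpochFiringStats:
    mean_rate: float  # Hz, trial-averaged
    variability: float  # Hz, trial-averaged SD of binned rate
    n_trials: int


def _n_bins(start: float, end: float, bin_s: float) -> int:
    # tolerance guards against 0.15/0.05 -> 2.999... style float loss
    return int(np.floor((end - start) / bin_s + 1e-9))


def _bin_counts(spike_times: np.ndarray, start: float, n_bins: int, bin_s: float):
    edges = start + np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(spike_times, bins=edges)
    return counts


def epoch_firing_stats(
    spike_times: np.ndarray,
    epochs: list[tuple[float, float]],
    bin_s: float = 0.010,
) -> EpochFiringStats:
    """Mean rate and rate SD from ``bin_s`` bins within each epoch, averaged
    over epochs (trials). Epochs shorter than one bin are skipped."""
    if len(epochs) == 0:
        raise ValueError("epochs must be non-empty")
    means, sds = [], []
    for start, end in epochs:
        n_bins = _n_bins(start, end, bin_s)
        if n_bins < 1:
            warnings.warn(f"epoch ({start:.3f}, {end:.3f}) shorter than one bin; skipped")
            continue
        rates = _bin_counts(spike_times, start, n_bins, bin_s) / bin_s
        means.append(rates.mean())
        sds.append(rates.std())
    if not means:
        return EpochFiringStats(float("nan"), float("nan"), 0)
    return EpochFiringStats(float(np.mean(means)), float(np.mean(sds)), len(means))


def bin_condition_labels(
    labels: np.ndarray, fs: float, start: float, n_bins: int, bin_s: float
) -> np.ndarray:
    """Majority label per bin; ties go to the lower code."""
    out = np.zeros(n_bins, dtype=np.int8)
    n_samp = len(labels)
    for b in range(n_bins):
        i0 = int(np.round((start + b * bin_s) * fs))
        i1 = int(np.round((start + (b + 1) * bin_s) * fs))
        seg = labels[max(i0, 0) : min(i1, n_samp)]
        if seg.size == 0:
            continue
        counts = np.bincount(seg, minlength=3)
        out[b] = int(np.argmax(counts))  # argmax breaks ties toward lower code
    return out


def burst_conditioned_firing(
    spike_times: np.ndarray,
    labels: np.ndarray,
    fs: float,
    epochs: list[tuple[float, float]],
    bin_s: float = 0.010,
) -> dict:
    """Per-condition (none/local/global) mean rate and variability over
    epoch bins, per trial then trial-averaged."""
    per_cond: dict[str, list[tuple[float, float]]] = {
        "none": [], "local": [], "global": []
    }
    names = {0: "none", 1: "local", 2: "global"}
    for start, end in epochs:
        n_bins = _n_bins(start, end, bin_s)
        if n_bins < 1:
            continue
        rates = _bin_counts(spike_times, start, n_bins, bin_s) / bin_s
        conds = bin_condition_labels(labels, fs, start, n_bins, bin_s)
        for code, name in names.items():
            sel = rates[conds == code]
            if sel.size == 0:
                continue  # this trial contributes nothing to this condition
            per_cond[name].append((sel.mean(), sel.std()))
    out = {}
    for name, vals in per_cond.items():
        if vals:
            arr = np.asarray(vals)
            out[name] = EpochFiringStats(
                float(arr[:, 0].mean()), float(arr[:, 1].mean()), len(vals)
            )
        else:
            out[name] = EpochFiringStats(float("nan"), float("nan"), 0)
    return out


# ---------------------------------------------------------------------------
# Phase entrainment
# ---------------------------------------------------------------------------


@dataclass
class EntrainmentResult:
    """Per unit x channel entrainment to one burst class in one epoch."""

    n_spikes: int
    r: np.ndarray  # (n_ch,) resultant vector length; NaN if n_spikes == 0
    shuffle_mean: np.ndarray
    shuffle_sd: np.ndarray
    shuffle_p95: np.ndarray
    z: np.ndarray  # modulation z-score
    significant: np.ndarray  # bool, r > 95th percentile of shuffle
    defined: bool  # False when the unit never spiked in-burst


def resultant_length(phases: np.ndarray) -> float:
    """Modulus of the mean unit phasor."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        return float("nan")
    return float(np.abs(np.exp(1j * phases).mean()))


def intersect_spans_with_epochs(
    spans: list[tuple[int, int]],
    epochs: list[tuple[float, float]],
    fs: float,
) -> list[tuple[int, int]]:
    """Clip sample-index spans to behavioral epochs (half-open on both sides)."""
    out = []
    for s, e in spans:
        for t0, t1 in epochs:
            i0 = max(s, int(np.round(t0 * fs)))
            i1 = min(e, int(np.round(t1 * fs)))
            if i1 > i0:
                out.append((i0, i1))
    return out


def phase_entrainment(
    spike_times: np.ndarray,
    phase: np.ndarray,
    fs: float,
    event_spans: list[tuple[int, int]],
    n_shuffles: int = 100,
    seed: int = 0,
) -> EntrainmentResult:
    """Entrainment of one unit to burst events on every LFP channel.

    ``event_spans`` are half-open sample-index spans of the burst class,
    already restricted to the behavioral epoch of interest. The null draws
    ``n_spikes`` phases (with replacement) from the pooled in-span phase
    samples per channel, ``n_shuffles`` times.
    """
    phase = np.atleast_2d(phase)
    n_ch, n_samp = phase.shape
    if len(event_spans) == 0:
        raise ValueError("need at least one event span")
    in_burst = np.zeros(n_samp, dtype=bool)
    for s, e in event_spans:
        in_burst[s:e] = True
    idx = np.round(np.asarray(spike_times, dtype=float) * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < n_samp)]
    spike_idx = idx[in_burst[idx]]
    n_spk = len(spike_idx)
    nan_arr = np.full(n_ch, np.nan)
    if n_spk == 0:
        return EntrainmentResult(
            0, nan_arr, nan_arr.copy(), nan_arr.copy(), nan_arr.copy(),
            nan_arr.copy(), np.zeros(n_ch, dtype=bool), defined=False,
        )
    rng = np.random.default_rng(seed)
    pool_idx = np.flatnonzero(in_burst)
    r = np.empty(n_ch)
    sh_mean = np.empty(n_ch)
    sh_sd = np.empty(n_ch)
    sh_p95 = np.empty(n_ch)
    phasors_all = np.exp(1j * phase)  # (n_ch, n_samp)
    for ch in range(n_ch):
        r[ch] = np.abs(phasors_all[ch, spike_idx].mean())
        draws = rng.choice(pool_idx, size=(n_shuffles, n_spk), replace=True)
        null_r = np.abs(phasors_all[ch][draws].mean(axis=1))
        sh_mean[ch] = null_r.mean()
        sh_sd[ch] = null_r.std()
        sh_p95[ch] = np.percentile(null_r, 95)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (r - sh_mean) / sh_sd
    return EntrainmentResult(
        n_spikes=n_spk,
        r=r,
        shuffle_mean=sh_mean,
        shuffle_sd=sh_sd,
        shuffle_p95=sh_p95,
        z=z,
        significant=r > sh_p95,
        defined=True,
    )


def entrainment_rate_association(
    results: dict,
    deltas: dict,
):
    """Pair each unit's median modulation z over significant channels with
    its firing-rate / variability change, and fit a descriptive OLS line.

    ``results``: unit -> EntrainmentResult (one burst class, one epoch).
    ``deltas``: unit -> (delta_rate, delta_variability), burst minus none.

    Units with no significant channel are excluded. Returns a DataFrame
    (unit, median_z, delta_rate, delta_variability) and a dict of
    regression summaries.
    """
    import pandas as pd
    from scipy import stats

    rows = []
    for unit, res in results.items():
        if not res.defined or not res.significant.any():
            continue
        if unit not in deltas:
            continue
        med_z = float(np.median(res.z[res.significant]))
        d_rate, d_var = deltas[unit]
        rows.append({"unit": unit, "median_z": med_z,
                     "delta_rate": d_rate, "delta_variability": d_var})
    table = pd.DataFrame(rows, columns=["unit", "median_z", "delta_rate",
                                        "delta_variability"])
    summary = {}
    for col in ("delta_rate", "delta_variability"):
        sub = table.dropna(subset=["median_z", col])
        if len(sub) >= 3:
            fit = stats.linregress(sub["median_z"], sub[col])
            tstat = fit.slope / fit.stderr if fit.stderr > 0 else float("nan")
            summary[col] = {"slope": fit.slope, "t": tstat,
                            "p": fit.pvalue, "n": len(sub)}
        else:
            summary[col] = {"slope": float("nan"), "t": float("nan"),
                            "p": float("nan"), "n": len(sub)}
    return table, summary


# ---------------------------------------------------------------------------
# Population dynamics model
# ---------------------------------------------------------------------------


@dataclass
class DynamicsModel:
    A: np.ndarray  # (n_units, n_units) transition matrix
    bin_s: float
    train_trials: np.ndarray
    unit_idx: np.ndarray
    rep: int = 0


def binned_rates(
    spike_times_list: list[np.ndarray],
    window: tuple[float, float],
    bin_s: float = 0.050,
) -> np.ndarray:
    """(n_units, n_bins) firing rates in ``bin_s`` bins over ``window``."""
    start, end = window
    n_bins = _n_bins(start, end, bin_s)
    out = np.empty((len(spike_times_list), n_bins))
    for i, st in enumerate(spike_times_list):
        out[i] = _bin_counts(np.asarray(st, dtype=float), start, n_bins, bin_s) / bin_s
    return out


def fit_linear_dynamics(trials: list[np.ndarray]) -> np.ndarray:
    """Least-squares A with X_t = A X_{t-1}, pairs stacked within trials only."""
    prev = np.concatenate([tr[:, :-1] for tr in trials], axis=1)
    nxt = np.concatenate([tr[:, 1:] for tr in trials], axis=1)
    if prev.shape[1] < prev.shape[0]:
        warnings.warn("fewer state pairs than units; A is underdetermined")
    at, *_ = np.linalg.lstsq(prev.T, nxt.T, rcond=None)
    return at.T


def predict_one_step(A: np.ndarray, trial: np.ndarray) -> np.ndarray:
    """Teacher-forced one-step predictions; column t predicts true bin t+1.

    Returns an (n_units, n_bins - 1) array aligned with ``trial[:, 1:]``.
    """
    return A @ trial[:, :-1]


def heldout_r2(A: np.ndarray, trials: list[np.ndarray]) -> float:
    """Pooled one-step R^2 over held-out trials (per-unit centering)."""
    true = np.concatenate([tr[:, 1:] for tr in trials], axis=1)
    pred = np.concatenate([predict_one_step(A, tr) for tr in trials], axis=1)
    sse = np.sum((true - pred) ** 2)
    sst = np.sum((true - true.mean(axis=1, keepdims=True)) ** 2)
    return float(1.0 - sse / sst) if sst > 0 else float("nan")


def fit_dynamics_model(
    trial_mats: list[np.ndarray],
    n_train_trials: int,
    n_units: int,
    n_reps: int = 200,
    bin_s: float = 0.050,
    seed: int = 0,
) -> list[DynamicsModel]:
    """Random trial/unit subsampling repeated ``n_reps`` times.

    ``trial_mats`` holds one (n_all_units, n_bins) rate matrix per trial.
    Each repetition subsamples ``n_units`` units and ``n_train_trials``
    training trials; held-out trials are every trial not used in training.
    """
    n_all_trials = len(trial_mats)
    n_all_units = trial_mats[0].shape[0] if n_all_trials else 0
    if n_all_trials <= n_train_trials:
        raise ValueError(
            f"need more than {n_train_trials} trials, got {n_all_trials}"
        )
    if n_all_units < n_units:
        raise ValueError(f"need at least {n_units} units, got {n_all_units}")
    rng = np.random.default_rng(seed)
    models = []
    for rep in range(n_reps):
        units = np.sort(rng.choice(n_all_units, size=n_units, replace=False))
        train = np.sort(rng.choice(n_all_trials, size=n_train_trials, replace=False))
        A = fit_linear_dynamics([trial_mats[t][units] for t in train])
        models.append(DynamicsModel(A=A, bin_s=bin_s, train_trials=train,
                                    unit_idx=units, rep=rep))
    return models


def category_predictability(
    true: np.ndarray,
    pred: np.ndarray,
    bin_labels: np.ndarray,
    min_bins: int = 2,
) -> dict:
    """Per-category R^2 for one trial.

    ``true``/``pred`` are (n_units, n_bins) arrays of true bins 1..T and
    their one-step predictions; ``bin_labels`` gives each bin's condition
    code. R^2 = 1 - SSE/SST with SST about the per-unit mean of that
    category's true bins. Categories with fewer than ``min_bins`` bins or
    zero-variance true bins yield NaN.
    """
    if true.shape != pred.shape:
        raise ValueError("true and pred must have the same shape")
    out = {}
    for code, name in ((0, "none"), (1, "local"), (2, "global")):
        sel = bin_labels == code
        if sel.sum() < min_bins:
            out[name] = float("nan")
            continue
        t = true[:, sel]
        p = pred[:, sel]
        sst = np.sum((t - t.mean(axis=1, keepdims=True)) ** 2)
        if sst == 0:
            out[name] = float("nan")
            continue
        out[name] = float(1.0 - np.sum((t - p) ** 2) / sst)
    return out
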