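"""Ground-truthed synthetic session generator.

Produces :class:`~betaburst.io.SessionBundle` objects with the statistical
structure the downstream analyses assume:

- per-channel 1/f background with a shared common-mode component;
- two injected burst classes: array-wide "global" events (higher amplitude,
  longer, lower frequency, usually coincident with subcortical bursting)
  and spatially clustered "local" events;
- Poisson spike trains with von Mises phase coupling to the injected
  oscillation and rate suppression during global events;
- bell-shaped reach speed profiles; inside global bursts the movement clock
  runs at ``slowdown_factor``, so speed drops and trials stretch.

Event scheduling is a renewal process with a guard gap, so events never
overlap on any channel and the ground truth is unambiguous.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import i0

from betaburst.config import SynthConfig
from betaburst.io import (
    BurstEventTruth,
    GroundTruth,
    Kinematics,
    SessionBundle,
    grid_geometry,
)

_EDGE_GUARD = 1.0  # s kept free of events at either session end
_SPIKE_DT = 0.001  # s, spike-generation resolution


# ---------------------------------------------------------------------------
# Background noise
# ---------------------------------------------------------------------------


def pink_noise(
    n_channels: int,
    n_samples: int,
    fs: float,
    exponent: float = 1.5,
    common_mode_frac: float = 0.2,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """1/f^exponent noise, unit variance per channel, with a shared component.

    The spectrum is flattened below 1 Hz to keep the variance finite.
    """
    from scipy.fft import irfft, next_fast_len

    rng = rng or np.random.default_rng()
    n_fft = next_fast_len(n_samples, real=True)  # pad; large primes are slow
    freqs = np.fft.rfftfreq(n_fft, 1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], 1.0) ** (-exponent / 2.0)
    shape[0] = 0.0

    shape32 = shape.astype(np.float32)

    def _one(seed_rows: int) -> np.ndarray:
        spec = np.empty((seed_rows, len(freqs)), dtype=np.complex64)
        spec.real = rng.standard_normal((seed_rows, len(freqs)), dtype=np.float32)
        spec.imag = rng.standard_normal((seed_rows, len(freqs)), dtype=np.float32)
        spec *= shape32[None, :]
        x = irfft(spec, n=n_fft, axis=1)[:, :n_samples]
        # single-pass scale to unit variance (mean is ~0 by construction)
        rms = np.sqrt(np.einsum("ij,ij->i", x, x) / x.shape[1])
        x /= rms[:, None]
        return x

    indep = _one(n_channels)
    if common_mode_frac > 0:
        shared = _one(1)
        out = (
            np.sqrt(1.0 - common_mode_frac) * indep
            + np.sqrt(common_mode_frac) * shared
        )
    else:
        out = indep
    return out


# ---------------------------------------------------------------------------
# Event scheduling and injection
# ---------------------------------------------------------------------------


def schedule_events(config: SynthConfig, rng: np.random.Generator) -> list[BurstEventTruth]:
    """Renewal schedule of non-overlapping global and local events."""
    total_rate = config.global_rate + config.local_rate
    if total_rate == 0:
        return []
    geometry = grid_geometry(config.grid_shape, config.x_spacing, config.y_spacing)
    min_span = _EDGE_GUARD + 0.2 + config.event_gap
    if config.session_duration < 2 * _EDGE_GUARD + 0.5:
        raise ValueError(
            f"session of {config.session_duration:g} s is too short to place events"
        )
    events: list[BurstEventTruth] = []
    t = _EDGE_GUARD
    p_global = config.global_rate / total_rate
    while True:
        t += rng.exponential(1.0 / total_rate)
        is_global = rng.random() < p_global
        params = config.global_params if is_global else config.local_params
        dur = float(
            np.clip(
                rng.normal(params.duration_mean, params.duration_sd),
                max(0.12, params.duration_mean / 2),
                params.duration_mean * 2,
            )
        )
        if t + dur > config.session_duration - _EDGE_GUARD:
            break
        if params.footprint == "all":
            # array-wide with per-event channel dropout, so the bursting
            # fraction forms a broad high mode instead of a spike at 1.0
            participation = rng.uniform(0.75, 0.95)
            take = rng.random(config.n_cortical_channels) < participation
            if take.sum() < 3:
                take[:3] = True
            channels = tuple(np.flatnonzero(take))
        else:
            center = rng.integers(config.n_cortical_channels)
            d = np.linalg.norm(geometry - geometry[center], axis=1)
            channels = tuple(np.flatnonzero(d <= params.cluster_radius_mm))
        sub_channels: tuple = ()
        if rng.random() < params.p_subcortical and config.n_subcortical_channels > 0:
            # large subsets keep subcortical envelope SDs burst-dominated
            lo = max(1, config.n_subcortical_channels // 2)
            n_sub = int(rng.integers(lo, config.n_subcortical_channels + 1))
            sub_channels = tuple(
                np.sort(rng.choice(config.n_subcortical_channels, n_sub, replace=False))
            )
        events.append(
            BurstEventTruth(
                category="global" if is_global else "local",
                start=t,
                end=t + dur,
                channels=channels,
                freq=float(params.freq_mean),
                phase0=float(rng.uniform(0, 2 * np.pi)),
                sub_channels=sub_channels,
            )
        )
        t += dur + config.event_gap
    return events


def inject_bursts(
    background: np.ndarray,
    events: list[BurstEventTruth],
    fs: float,
    amplitude_by_class: dict,
    subcortex: bool = False,
) -> np.ndarray:
    """Add Hann-enveloped sinusoids for each event to the involved channels.

    With ``subcortex=True``, injection targets each event's ``sub_channels``
    instead of its cortical channel set. Returns a modified copy.
    """
    out = np.array(background, dtype=background.dtype, copy=True)
    n_samples = out.shape[1]
    for ev in events:
        i0_, i1 = int(round(ev.start * fs)), int(round(ev.end * fs))
        if i0_ < 0 or i1 > n_samples:
            raise ValueError(
                f"event ({ev.start:g}, {ev.end:g}) s outside the signal span"
            )
        n = i1 - i0_
        if n <= 0:
            continue
        tt = np.arange(n) / fs
        env = 0.5 * (1.0 - np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1)))
        wave = (
            amplitude_by_class[ev.category]
            * env
            * np.sin(2 * np.pi * ev.freq * tt + ev.phase0)
        ).astype(out.dtype)
        channels = list(ev.sub_channels if subcortex else ev.channels)
        out[channels, i0_:i1] += wave[None, :]
    return out


# ---------------------------------------------------------------------------
# Spikes
# ---------------------------------------------------------------------------


def build_phase_reference(
    events: list[BurstEventTruth], duration: float, dt: float = _SPIKE_DT
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin oscillation phase and class code (0 none, 1 local, 2 global).

    The phase matches the analytic-signal convention of the injected
    sinusoid (``sin(theta)`` has analytic phase ``theta - pi/2``), so
    preferred phases in the ground truth line up with measured phases.
    """
    n = int(round(duration / dt))
    phase = np.full(n, np.nan)
    code = np.zeros(n, dtype=np.int8)
    centers = (np.arange(n) + 0.5) * dt
    for ev in events:
        i0_, i1 = int(ev.start / dt), min(int(np.ceil(ev.end / dt)), n)
        tt = centers[i0_:i1] - ev.start
        theta = 2 * np.pi * ev.freq * tt + ev.phase0 - np.pi / 2
        phase[i0_:i1] = np.angle(np.exp(1j * theta))
        code[i0_:i1] = 2 if ev.category == "global" else 1
    return phase, code


def generate_entrained_spikes(
    phase: np.ndarray,
    class_code: np.ndarray,
    config: SynthConfig,
    rng: np.random.Generator,
    dt: float = _SPIKE_DT,
) -> tuple[dict, dict]:
    """Inhomogeneous Bernoulli spike trains coupled to the event phase.

    Inside events the intensity is the base rate times
    ``exp(kappa * cos(phase - preferred)) / I0(kappa)`` (unit mean over
    phase), scaled additionally by the class ``rate_scale``.
    """
    for params in (config.global_params, config.local_params):
        if params.kappa < 0:
            raise ValueError("kappa must be >= 0")
    n = len(phase)
    spikes: dict = {}
    coupling: dict = {}
    kg, kl = config.global_params.kappa, config.local_params.kappa
    sg = config.global_params.rate_scale
    sl = config.local_params.rate_scale
    in_g = class_code == 2
    in_l = class_code == 1
    centers = (np.arange(n) + 0.5) * dt
    for u in range(config.n_units):
        theta = float(rng.uniform(-np.pi, np.pi))
        mod = np.ones(n)
        if in_g.any():
            mod[in_g] = sg * np.exp(kg * np.cos(phase[in_g] - theta)) / i0(kg)
        if in_l.any():
            mod[in_l] = sl * np.exp(kl * np.cos(phase[in_l] - theta)) / i0(kl)
        p = np.clip(config.base_rate * dt * mod, 0.0, 0.95)
        fired = rng.random(n) < p
        spikes[f"u{u:03d}"] = centers[fired]
        coupling[f"u{u:03d}"] = {
            "preferred_phase": theta,
            "kappa_global": kg,
            "kappa_local": kl,
        }
    return spikes, coupling


def make_waveforms(
    n_units: int, rng: np.random.Generator, n_taps: int = 40
) -> dict:
    """Biphasic average waveforms; a ~10% minority gets sub-threshold SNR."""
    t = np.arange(n_taps)
    trough = np.exp(-0.5 * ((t - 16) / 2.0) ** 2)
    peak = np.exp(-0.5 * ((t - 24) / 3.0) ** 2)
    template = -trough + 0.55 * peak
    out = {}
    for u in range(n_units):
        snr_target = 1.5 if rng.random() < 0.1 else rng.uniform(6.0, 14.0)
        ptp = template.max() - template.min()
        noise_sd = ptp / snr_target
        mean = template + rng.normal(0, noise_sd * 0.05, n_taps)
        out[f"u{u:03d}"] = (mean * 80.0, np.full(n_taps, noise_sd * 80.0))
    return out


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------


def _bell_sigma(duration: float, peak_frac: float = 0.1) -> float:
    """Gaussian SD such that the bell hits peak_frac x peak at +/-duration/2."""
    return duration / (2.0 * np.sqrt(2.0 * np.log(1.0 / peak_frac)))


def generate_trial_kinematics(
    trial_starts: np.ndarray,
    slowdown_intervals: list[tuple[float, float]],
    config: SynthConfig,
    rng: np.random.Generator,
) -> tuple[Kinematics, pd.DataFrame]:
    """Per-trial reach/grasp kinematics with clock-warped slowdowns.

    ``trial_starts`` are door-open times. From each reach start the movement
    follows a canonical profile: a speed bell over the reach, a quiet gap,
    then manipulation wiggles until the object lift. Inside slowdown
    intervals the canonical clock advances at ``slowdown_factor``, which
    lowers speed and stretches the trial. Returns the position trace and the
    ground-truth trial table.
    """
    fr = config.frame_rate
    dt = 1.0 / fr
    duration = config.session_duration
    n_frames = int(round(duration * fr))
    frame_times = np.arange(n_frames) * dt
    peak = config.peak_speed
    reach_dur = config.reach_nominal
    grasp_dur = config.grasp_nominal
    sigma = _bell_sigma(reach_dur)
    s_total = reach_dur + grasp_dur
    manip_gap = 0.3  # quiet canonical seconds after grasp start
    max_movement = 5.0  # s real-time cap on the warped movement

    slow = np.zeros(n_frames, dtype=bool)
    for t0, t1 in slowdown_intervals:
        i0_, i1 = int(t0 * fr), int(np.ceil(t1 * fr))
        slow[max(i0_, 0) : min(i1, n_frames)] = True

    def canonical_speed(s: float) -> float:
        if s < reach_dur:
            return peak * np.exp(-0.5 * ((s - reach_dur / 2) / sigma) ** 2)
        if s < reach_dur + manip_gap:
            return 0.0
        if s < s_total:
            u = s - reach_dur - manip_gap
            return 0.3 * peak * np.sin(2 * np.pi * 1.5 * u) ** 2
        return 0.0

    vel = np.zeros((n_frames, 2))
    rest = np.array([0.0, 0.0])
    rows = []
    slots = ["power", "pinch", "tripod", "precision"]
    reach_displacement = peak * sigma * np.sqrt(2 * np.pi)
    crossing_x = rest[0] + 0.5 * reach_displacement

    for k, door_open in enumerate(trial_starts):
        reach_start = door_open + 0.5
        i = int(round(reach_start * fr))
        s = 0.0
        grasp_start = np.nan
        last_lift = np.nan
        x_travel = 0.0
        y_travel = 0.0
        while i < n_frames and s < s_total and (i * dt - reach_start) < max_movement:
            rate = config.slowdown_factor if slow[i] else 1.0
            v = canonical_speed(s) * rate
            if s < reach_dur:
                vel[i, 0] += v
                x_travel += v * dt
            else:
                vel[i, 1] += v * (1 if int(s * 3) % 2 == 0 else -1)
                y_travel += v * dt
            s += rate * dt
            if np.isnan(grasp_start) and s >= reach_dur:
                grasp_start = (i + 1) * dt
            i += 1
        if s >= s_total:
            last_lift = i * dt
        # return stroke: straight back to rest over 1.5 s
        if np.isfinite(last_lift):
            ret_start = last_lift + 0.4
            ret_dur = 1.5
            d = np.hypot(x_travel, y_travel)
            if d > 0:
                ux, uy = -x_travel / d, -y_travel / d
                sig_r = _bell_sigma(ret_dur)
                peak_r = d / (sig_r * np.sqrt(2 * np.pi))
                j0 = int(round(ret_start * fr))
                j1 = min(int(round((ret_start + ret_dur) * fr)), n_frames)
                tt = np.arange(j0, j1) * dt
                vr = peak_r * np.exp(
                    -0.5 * ((tt - (ret_start + ret_dur / 2)) / sig_r) ** 2
                )
                if vr.sum() > 0:
                    vr *= d / (vr.sum() * dt)  # cancel travel exactly: no drift
                vel[j0:j1, 0] += ux * vr
                vel[j0:j1, 1] += uy * vr
        rewarded = bool(rng.random() < config.p_rewarded) and np.isfinite(last_lift)
        reward_time = last_lift + 0.267 if rewarded else np.nan
        rows.append(
            {
                "trial": k,
                "slot": slots[k % len(slots)],
                "door_open": door_open,
                "reach_start": reach_start,
                "grasp_start": grasp_start,
                "first_lift": last_lift,
                "last_lift": last_lift,
                "reward_time": reward_time,
                "rewarded": rewarded,
            }
        )

    position = rest[None, :] + np.cumsum(vel * dt, axis=0)
    position += rng.normal(0.0, 0.0005 * reach_displacement, position.shape)
    kin = Kinematics(
        frame_times=frame_times, position=position, crossing_x=float(crossing_x)
    )
    return kin, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full session
# ---------------------------------------------------------------------------


def generate_session(
    config: SynthConfig, session_id: str = "synthetic"
) -> tuple[SessionBundle, GroundTruth]:
    """Generate one complete session bundle plus its ground truth.

    Deterministic in ``config.seed``: identical configs give bit-identical
    bundles.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs_raw
    n_samples = int(round(config.session_duration * fs))

    events = schedule_events(config, rng)
    amp = {
        "global": config.global_params.amplitude,
        "local": config.local_params.amplitude,
    }

    cortex = pink_noise(
        config.n_cortical_channels, n_samples, fs,
        config.noise_exponent, config.common_mode_frac, rng,
    ) * config.noise_std
    cortex = inject_bursts(cortex, events, fs, amp).astype(np.float32)

    subcortex = pink_noise(
        config.n_subcortical_channels, n_samples, fs,
        config.noise_exponent, config.common_mode_frac, rng,
    ) * config.noise_std
    subcortex = inject_bursts(subcortex, events, fs, amp, subcortex=True).astype(
        np.float32
    )

    phase_ref, class_code = build_phase_reference(events, config.session_duration)
    spikes, coupling = generate_entrained_spikes(phase_ref, class_code, config, rng)
    waveforms = make_waveforms(config.n_units, rng)

    trial_starts = np.arange(
        config.first_trial_time,
        config.session_duration - config.trial_period,
        config.trial_period,
    )
    slowdowns = [(e.start, e.end) for e in events if e.category == "global"]
    kin, trial_truth = generate_trial_kinematics(trial_starts, slowdowns, config, rng)

    long_rows = []
    for _, row in trial_truth.iterrows():
        for name in ("door_open", "reach_start", "grasp_start", "first_lift",
                     "last_lift", "reward_time"):
            if np.isfinite(row[name]):
                long_rows.append(
                    {"trial": int(row["trial"]), "event_name": name,
                     "time_s": float(row[name])}
                )
    trial_events = pd.DataFrame(long_rows, columns=["trial", "event_name", "time_s"])
    trial_meta = trial_truth[["trial", "slot", "rewarded"]].copy()

    bundle = SessionBundle(
        lfp_cortex=cortex,
        lfp_subcortex=subcortex,
        fs=fs,
        geometry=grid_geometry(config.grid_shape, config.x_spacing, config.y_spacing),
        spikes=spikes,
        waveforms=waveforms,
        trial_events=trial_events,
        trial_meta=trial_meta,
        kinematics=kin,
        beta_band=config.beta_band,
        session_id=session_id,
    )
    truth = GroundTruth(
        burst_events=events,
        spike_coupling=coupling,
        trial_truth=trial_truth,
        slowdown_intervals=slowdowns,
    )
    return bundle, truth
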