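"""Configuration dataclasses shared across the pipeline.

All defaults follow the analysis conventions pinned for this pipeline:
100 ms minimum burst duration, 3-channel minimum for a cortical burst
timepoint, 100 shuffles, 50 ms dynamics bins, 200 subsample repetitions,
+/-0.35 s behavioral alignment windows, the 0.1 x peak-speed rule and a
10 s trial timeout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml


@dataclass
class BurstClassParams:
    """Parameters of one injected burst class (global or local).

    ``footprint`` is ``"all"`` for array-wide (global) events or
    ``"cluster"`` for spatially clustered (local) events with
    ``cluster_radius_mm`` around a randomly drawn center channel.
    """

    amplitude: float
    duration_mean: float  # s
    duration_sd: float  # s
    freq_mean: float  # Hz
    footprint: str = "all"  # "all" | "cluster"
    cluster_radius_mm: float = 0.6
    p_subcortical: float = 0.9  # probability of a coincident subcortical burst
    kappa: float = 1.0  # von Mises spike-coupling concentration
    rate_scale: float = 1.0  # multiplicative firing-rate factor inside events

    def validate(self, beta_band: tuple[float, float]) -> None:
        if self.duration_mean < 0.1:
            raise ValueError("duration_mean must be >= 0.1 s")
        if not (beta_band[0] <= self.freq_mean <= beta_band[1]):
            raise ValueError("freq_mean must lie inside beta_band")
        if self.footprint not in ("all", "cluster"):
            raise ValueError(f"unknown footprint {self.footprint!r}")


def _default_global_params() -> BurstClassParams:
    return BurstClassParams(
        amplitude=8.0,
        duration_mean=0.40,
        duration_sd=0.08,
        freq_mean=18.0,
        footprint="all",
        p_subcortical=0.9,
        kappa=1.5,
        rate_scale=0.5,
    )


def _default_local_params() -> BurstClassParams:
    return BurstClassParams(
        amplitude=2.5,
        duration_mean=0.20,
        duration_sd=0.04,
        freq_mean=27.0,
        footprint="cluster",
        cluster_radius_mm=0.6,
        p_subcortical=0.1,
        kappa=0.5,
        rate_scale=1.0,
    )


@dataclass
class SynthConfig:
    """Full parameterisation of one synthetic session."""

    n_cortical_channels: int = 64  # laid out grid_shape row-major
    n_subcortical_channels: int = 32
    grid_shape: tuple[int, int] = (8, 8)
    fs_raw: float = 3051.8
    x_spacing: float = 0.5  # mm, electrode (column) pitch
    y_spacing: float = 0.375  # mm, row pitch
    session_duration: float = 300.0  # s
    beta_band: tuple[float, float] = (15.0, 35.0)
    global_rate: float = 0.15  # events / s
    local_rate: float = 0.30  # events / s
    global_params: BurstClassParams = field(default_factory=_default_global_params)
    local_params: BurstClassParams = field(default_factory=_default_local_params)
    event_gap: float = 0.15  # s guard between scheduled events
    n_units: int = 20
    base_rate: float = 8.0  # Hz
    noise_exponent: float = 1.5  # 1/f^alpha background slope
    common_mode_frac: float = 0.2  # shared background fraction
    noise_std: float = 1.0
    # behavior
    frame_rate: float = 50.0
    trial_period: float = 9.0  # s between door-open events
    first_trial_time: float = 5.0
    reach_nominal: float = 0.8  # s, reach-start -> grasp-start
    grasp_nominal: float = 1.2  # s, grasp-start -> lift
    peak_speed: float = 20.0  # arbitrary position units / s
    slowdown_factor: float = 0.3  # movement-clock rate inside global bursts
    p_rewarded: float = 0.85
    seed: int = 0

    def validate(self) -> None:
        if self.x_spacing <= 0 or self.y_spacing <= 0:
            raise ValueError("spacings must be > 0")
        if self.global_rate < 0 or self.local_rate < 0:
            raise ValueError("rates must be >= 0")
        lo, hi = self.beta_band
        if not (0 < lo < hi < self.fs_raw / 2):
            raise ValueError("need 0 < beta low < beta high < fs_raw/2")
        if self.grid_shape[0] * self.grid_shape[1] != self.n_cortical_channels:
            raise ValueError("grid_shape inconsistent with n_cortical_channels")
        self.global_params.validate(self.beta_band)
        self.local_params.validate(self.beta_band)


@dataclass
class PipelineConfig:
    """Analysis-side constants; defaults are the pipeline's printed values."""

    beta_band: tuple[float, float] = (15.0, 35.0)
    filter_order: int = 3
    decimation_factor: int = 3
    min_burst_duration: float = 0.100  # s
    min_channels: int = 3
    n_shuffles: int = 100
    dynamics_bin: float = 0.050  # s
    dynamics_n_trials: int = 8
    dynamics_n_units: int = 12
    dynamics_n_reps: int = 200
    firing_bin: float = 0.010  # s
    entrainment_bin: float = 0.001  # s
    alignment_window: float = 0.35  # s, +/- around behavioral events
    trial_window: tuple[float, float] = (-3.0, 10.0)  # s around reach start
    speed_peak_frac: float = 0.1  # onset/offset rule: speed < frac x peak
    trial_timeout: float = 10.0  # s
    early_late_threshold: float = 0.5  # recovery-index split
    excluded_channels: tuple[int, ...] = ()
    auto_exclude_k: Optional[float] = None  # exclude if env SD > k x median SD
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.beta_band = tuple(cfg.beta_band)  # type: ignore[assignment]
        cfg.trial_window = tuple(cfg.trial_window)  # type: ignore[assignment]
        cfg.excluded_channels = tuple(cfg.excluded_channels)
        return cfg

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["beta_band"] = list(self.beta_band)
        d["trial_window"] = list(self.trial_window)
        d["excluded_channels"] = list(self.excluded_channels)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def synth_config_from_yaml(path: str) -> SynthConfig:
    """Load a :class:`SynthConfig` from YAML, nesting class params."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("global_params", "local_params"):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = BurstClassParams(**raw[key])
    for key in ("beta_band", "grid_shape"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = SynthConfig(**raw)
    cfg.validate()
    return cfg
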