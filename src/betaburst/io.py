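"""Session bundle containers and HDF5 / TSV serialisation.

HDF5 layout::

    /lfp/cortex          (n_ch, n_samp) float32
    /lfp/subcortex       (n_ch, n_samp) float32
    /spikes/<unit>       (n_spikes,) float64 spike times in s
    /waveforms/<unit>/mean, /waveforms/<unit>/sd
    /kinematics/frame_times, /kinematics/position  (n_frames, 2)
    /geometry            (n_ch, 2) float64, mm
    /trials/...          long-format event table
    attrs: fs, beta_band, crossing_x

All times are seconds from session start; sample intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import h5py
import numpy as np
import pandas as pd


@dataclass
class Kinematics:
    frame_times: np.ndarray  # (n_frames,) s
    position: np.ndarray  # (n_frames, 2)
    crossing_x: float  # apparatus front-panel line

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.frame_times)))


@dataclass
class SessionBundle:
    """All raw inputs for one behavioral day."""

    lfp_cortex: np.ndarray  # (n_ch, n_samp)
    lfp_subcortex: np.ndarray
    fs: float
    geometry: np.ndarray  # (n_cortical_ch, 2) mm
    spikes: dict  # unit id -> spike times (s)
    waveforms: dict  # unit id -> (mean, sd) arrays
    trial_events: pd.DataFrame  # columns: trial, event_name, time_s
    trial_meta: pd.DataFrame  # columns: trial, slot, rewarded
    kinematics: Kinematics
    beta_band: tuple[float, float] = (15.0, 35.0)
    session_id: str = "session"

    @property
    def n_cortical_channels(self) -> int:
        return self.lfp_cortex.shape[0]

    @property
    def n_samples(self) -> int:
        return self.lfp_cortex.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def event_times(self, event_name: str) -> pd.Series:
        """Per-trial times of one named event, indexed by trial."""
        sub = self.trial_events[self.trial_events["event_name"] == event_name]
        return sub.set_index("trial")["time_s"]


@dataclass
class BurstEventTruth:
    category: str  # "global" | "local"
    start: float  # s
    end: float  # s
    channels: tuple  # involved cortical channel ids
    freq: float  # injected oscillation frequency, Hz
    phase0: float  # oscillation phase at event start, rad
    sub_channels: tuple = ()  # coincident subcortical channels


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery scoring."""

    burst_events: list  # of BurstEventTruth
    spike_coupling: dict  # unit -> {"preferred_phase", "kappa_global", "kappa_local"}
    trial_truth: pd.DataFrame  # trial, reach_start, grasp_start, last_lift, ...
    slowdown_intervals: list = field(default_factory=list)  # (start, end) s

    def events_of(self, category: str) -> list:
        return [e for e in self.burst_events if e.category == category]


def write_session(path: str, bundle: SessionBundle) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = bundle.fs
        f.attrs["beta_band"] = np.asarray(bundle.beta_band, dtype=float)
        f.attrs["session_id"] = bundle.session_id
        f.attrs["crossing_x"] = bundle.kinematics.crossing_x
        lfp = f.create_group("lfp")
        lfp.create_dataset("cortex", data=bundle.lfp_cortex.astype(np.float32))
        lfp.create_dataset("subcortex", data=bundle.lfp_subcortex.astype(np.float32))
        f.create_dataset("geometry", data=np.asarray(bundle.geometry, dtype=float))
        sp = f.create_group("spikes")
        wf = f.create_group("waveforms")
        for unit, times in bundle.spikes.items():
            sp.create_dataset(str(unit), data=np.asarray(times, dtype=float))
            mean, sd = bundle.waveforms[unit]
            g = wf.create_group(str(unit))
            g.create_dataset("mean", data=np.asarray(mean, dtype=float))
            g.create_dataset("sd", data=np.asarray(sd, dtype=float))
        kin = f.create_group("kinematics")
        kin.create_dataset("frame_times", data=bundle.kinematics.frame_times)
        kin.create_dataset("position", data=bundle.kinematics.position)
        tr = f.create_group("trials")
        tr.create_dataset("trial", data=bundle.trial_events["trial"].to_numpy(int))
        names = bundle.trial_events["event_name"].astype(str).to_numpy()
        tr.create_dataset("event_name", data=names.astype("S"))
        tr.create_dataset("time_s", data=bundle.trial_events["time_s"].to_numpy(float))
        tm = f.create_group("trial_meta")
        tm.create_dataset("trial", data=bundle.trial_meta["trial"].to_numpy(int))
        tm.create_dataset("slot", data=bundle.trial_meta["slot"].astype(str).to_numpy().astype("S"))
        tm.create_dataset("rewarded", data=bundle.trial_meta["rewarded"].to_numpy(bool))


def read_session(path: str) -> SessionBundle:
    with h5py.File(path, "r") as f:
        spikes = {u: f["spikes"][u][...] for u in f["spikes"]}
        waveforms = {
            u: (f["waveforms"][u]["mean"][...], f["waveforms"][u]["sd"][...])
            for u in f["waveforms"]
        }
        trial_events = pd.DataFrame(
            {
                "trial": f["trials/trial"][...].astype(int),
                "event_name": [s.decode() for s in f["trials/event_name"][...]],
                "time_s": f["trials/time_s"][...].astype(float),
            }
        )
        trial_meta = pd.DataFrame(
            {
                "trial": f["trial_meta/trial"][...].astype(int),
                "slot": [s.decode() for s in f["trial_meta/slot"][...]],
                "rewarded": f["trial_meta/rewarded"][...].astype(bool),
            }
        )
        kin = Kinematics(
            frame_times=f["kinematics/frame_times"][...],
            position=f["kinematics/position"][...],
            crossing_x=float(f.attrs["crossing_x"]),
        )
        return SessionBundle(
            lfp_cortex=f["lfp/cortex"][...],
            lfp_subcortex=f["lfp/subcortex"][...],
            fs=float(f.attrs["fs"]),
            geometry=f["geometry"][...],
            spikes=spikes,
            waveforms=waveforms,
            trial_events=trial_events,
            trial_meta=trial_meta,
            kinematics=kin,
            beta_band=tuple(f.attrs["beta_band"]),
            session_id=str(f.attrs["session_id"]),
        )


def write_tsv(df: pd.DataFrame, path: str) -> None:
    """Deterministic TSV output (fixed float format, no index)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def grid_geometry(
    grid_shape: tuple[int, int] = (8, 8),
    x_spacing: float = 0.5,
    y_spacing: float = 0.375,
) -> np.ndarray:
    """Row-major (x, y) coordinates in mm of a rectangular electrode grid.

    Channel 0 sits at the origin; channel ``i`` at row ``i // n_cols``,
    column ``i % n_cols``.
    """
    n_rows, n_cols = grid_shape
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    return np.column_stack([cols * x_spacing, rows * y_spacing]).astype(float)
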