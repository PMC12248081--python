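"""End-to-end orchestration over one or more session bundles.

``run_pipeline`` executes every stage on each session, pools the
bursting-fraction distributions across sessions to fit a single
local/global threshold (one threshold for all days), and writes
deterministic TSV tables plus a machine-readable manifest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from betaburst import behavior as bh
from betaburst import burst_classify as bc
from betaburst import burst_detect as bd
from betaburst import lfp_preprocess as lp
from betaburst import spatial_stats as ss
from betaburst import spike_analysis as sa
from betaburst.config import PipelineConfig
from betaburst.io import SessionBundle, read_session, write_tsv


@dataclass
class SessionStage:
    """Per-session intermediate products of the detection stages."""

    bundle: SessionBundle
    fs: float
    analytic: lp.AnalyticBetaSeries
    included: np.ndarray  # cortical channel keep-mask
    channel_events: list
    masks: np.ndarray
    sub_masks: np.ndarray
    fractions: bc.FractionSeries
    labels: np.ndarray | None = None
    population_events: list = field(default_factory=list)


def detect_stage(bundle: SessionBundle, cfg: PipelineConfig) -> SessionStage:
    """Decimate, band-limit, threshold and detect per-channel bursts."""
    dec, fs = lp.decimate_lfp(bundle.lfp_cortex, bundle.fs, cfg.decimation_factor)
    analytic = lp.analytic_beta(dec, cfg.beta_band, fs, cfg.filter_order)
    included = lp.exclude_noisy_channels(
        analytic.amplitude, cfg.excluded_channels, cfg.auto_exclude_k
    )
    thresholds = bd.compute_channel_thresholds(analytic.amplitude)
    events = bd.detect_channel_bursts(
        analytic.amplitude, thresholds, fs, phase=analytic.phase,
        min_duration=cfg.min_burst_duration,
    )
    events = [e for e in events if included[e.channel]]
    masks = bd.burst_masks(events, bundle.n_cortical_channels, dec.shape[1])

    sub_dec, _ = lp.decimate_lfp(bundle.lfp_subcortex, bundle.fs, cfg.decimation_factor)
    sub_analytic = lp.analytic_beta(sub_dec, cfg.beta_band, fs, cfg.filter_order)
    sub_thresholds = bd.compute_channel_thresholds(sub_analytic.amplitude)
    sub_events = bd.detect_channel_bursts(
        sub_analytic.amplitude, sub_thresholds, fs,
        min_duration=cfg.min_burst_duration,
    )
    sub_masks = bd.burst_masks(sub_events, sub_dec.shape[0], sub_dec.shape[1])

    fractions = bc.fraction_bursting(masks, included)
    return SessionStage(
        bundle=bundle,
        fs=fs,
        analytic=analytic,
        included=included,
        channel_events=events,
        masks=masks,
        sub_masks=sub_masks,
        fractions=fractions,
    )


def classify_stage(
    stages: list[SessionStage], cfg: PipelineConfig
) -> bc.LocalGlobalThreshold:
    """One threshold fitted on all sessions, then labels/events per session."""
    per_day = [
        st.fractions.fraction[st.fractions.count >= cfg.min_channels]
        for st in stages
    ]
    fit = bc.fit_local_global_threshold(per_day, seed=cfg.seed)
    for st in stages:
        # excluded channels carry all-False masks (their events were dropped),
        # so full-size fracact rows for them are zero and harmless
        st.labels, st.population_events = bc.label_and_segment(
            st.fractions, fit.threshold, st.masks,
            st.fs, cfg.min_channels, cfg.min_burst_duration,
        )
    return fit


def behavior_stage(stage: SessionStage, cfg: PipelineConfig) -> pd.DataFrame:
    """Kinematic event extraction per trial; falls back to NaN on failure."""
    bundle = stage.bundle
    kin = bundle.kinematics
    door_open = bundle.event_times("door_open")
    rows = []
    meta = bundle.trial_meta.set_index("trial")
    for trial, t0 in door_open.items():
        t_end = t0 + cfg.trial_timeout + 2.0
        m = (kin.frame_times >= t0) & (kin.frame_times < t_end)
        res = bh.detect_reach_grasp_events(
            kin.position[m], kin.frame_times[m], kin.crossing_x,
            trial=int(trial), peak_frac=cfg.speed_peak_frac,
        )
        reward = bundle.event_times("reward_time").get(trial, np.nan)
        rows.append(
            {
                "trial": int(trial),
                "slot": meta.loc[trial, "slot"],
                "rewarded": bool(meta.loc[trial, "rewarded"]),
                "door_open": float(t0),
                "reach_start": res.reach_start,
                "grasp_start": res.grasp_start,
                "reward_time": float(reward),
                "last_lift": bundle.event_times("last_lift").get(trial, np.nan),
                "crossing_time": res.crossing_time,
                "peak_speed": res.peak_speed,
            }
        )
    return pd.DataFrame(rows)


def spike_stage(
    stage: SessionStage, trials: pd.DataFrame, cfg: PipelineConfig
) -> dict:
    """Firing statistics, entrainment and associations during grasping."""
    bundle = stage.bundle
    units = sa.make_unit_records(bundle.spikes, bundle.waveforms, bundle.duration)
    _, grasp_ep = bh.define_epochs(trials, cfg.trial_timeout)
    epochs = list(grasp_ep.values())
    firing_rows = []
    deltas: dict[str, dict] = {"local": {}, "global": {}}
    for rec in units:
        if not rec.included or not epochs:
            continue
        cond = sa.burst_conditioned_firing(
            rec.spike_times, stage.labels, stage.fs, epochs, cfg.firing_bin
        )
        for name, stats in cond.items():
            firing_rows.append(
                {
                    "unit": rec.unit,
                    "condition": name,
                    "mean_rate_hz": stats.mean_rate,
                    "rate_variability_hz": stats.variability,
                    "n_trials": stats.n_trials,
                }
            )
        for cat in ("local", "global"):
            deltas[cat][rec.unit] = (
                cond[cat].mean_rate - cond["none"].mean_rate,
                cond[cat].variability - cond["none"].variability,
            )
    entrain_rows = []
    assoc = {}
    for cat in ("local", "global"):
        spans = [
            (e.start_idx, e.stop_idx)
            for e in stage.population_events
            if e.category == cat
        ]
        spans = sa.intersect_spans_with_epochs(spans, epochs, stage.fs)
        results = {}
        if spans:
            for rec in units:
                if not rec.included:
                    continue
                res = sa.phase_entrainment(
                    rec.spike_times, stage.analytic.phase, stage.fs, spans,
                    n_shuffles=cfg.n_shuffles, seed=cfg.seed,
                )
                results[rec.unit] = res
                if res.defined:
                    entrain_rows.append(
                        {
                            "unit": rec.unit,
                            "class": cat,
                            "n_spikes": res.n_spikes,
                            "median_r": float(np.nanmedian(res.r)),
                            "median_z": float(np.nanmedian(res.z)),
                            "n_significant_channels": int(res.significant.sum()),
                        }
                    )
        table, summary = sa.entrainment_rate_association(results, deltas[cat])
        assoc[cat] = {"table": table, "summary": summary}
    return {
        "units": units,
        "firing": pd.DataFrame(firing_rows),
        "entrainment": pd.DataFrame(entrain_rows),
        "association": assoc,
    }


def dynamics_stage(
    stage: SessionStage, trials: pd.DataFrame, cfg: PipelineConfig
) -> pd.DataFrame | None:
    """Subsampled dynamics fits with per-category held-out R^2.

    Returns None (with a warning) when the session has too few rewarded
    trials or included units for the configured subsample sizes.
    """
    units = [
        rec for rec in sa.make_unit_records(
            stage.bundle.spikes, stage.bundle.waveforms, stage.bundle.duration
        )
        if rec.included
    ]
    ok = trials[
        trials["rewarded"]
        & np.isfinite(trials["reach_start"])
        & np.isfinite(trials["last_lift"])
    ]
    windows = [
        (row["reach_start"] - 0.5, row["last_lift"]) for _, row in ok.iterrows()
    ]
    windows = [w for w in windows if w[1] - w[0] >= 2 * cfg.dynamics_bin]
    if len(windows) <= cfg.dynamics_n_trials or len(units) < cfg.dynamics_n_units:
        warnings.warn(
            f"dynamics model skipped: {len(windows)} usable trials / "
            f"{len(units)} units below configured minimums"
        )
        return None
    spike_lists = [rec.spike_times for rec in units]
    mats = [sa.binned_rates(spike_lists, w, cfg.dynamics_bin) for w in windows]
    models = sa.fit_dynamics_model(
        mats, cfg.dynamics_n_trials, cfg.dynamics_n_units,
        n_reps=cfg.dynamics_n_reps, bin_s=cfg.dynamics_bin, seed=cfg.seed,
    )
    rows = []
    for model in models:
        held = [t for t in range(len(mats)) if t not in set(model.train_trials)]
        r2s = {"none": [], "local": [], "global": []}
        overall = []
        for t in held:
            mat = mats[t][model.unit_idx]
            pred = sa.predict_one_step(model.A, mat)
            start = windows[t][0]
            n_bins = mat.shape[1]
            bin_labels = sa.bin_condition_labels(
                stage.labels, stage.fs, start, n_bins, cfg.dynamics_bin
            )
            out = sa.category_predictability(mat[:, 1:], pred, bin_labels[1:])
            for k, v in out.items():
                if np.isfinite(v):
                    r2s[k].append(v)
            overall.append(sa.heldout_r2(model.A, [mat]))
        rows.append(
            {
                "rep": model.rep,
                "heldout_r2": float(np.mean(overall)),
                "r2_none": float(np.mean(r2s["none"])) if r2s["none"] else np.nan,
                "r2_local": float(np.mean(r2s["local"])) if r2s["local"] else np.nan,
                "r2_global": float(np.mean(r2s["global"])) if r2s["global"] else np.nan,
                "n_valid_none": len(r2s["none"]),
                "n_valid_local": len(r2s["local"]),
                "n_valid_global": len(r2s["global"]),
            }
        )
    return pd.DataFrame(rows)


_ALIGN_EVENTS = ("door_open", "reach_start", "grasp_start", "last_lift",
                 "reward_time")


def behavior_summary_stage(
    stage: SessionStage, trials: pd.DataFrame, cfg: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Alignment fractions and burst occupancy per category."""
    align_rows, occ_rows = [], []
    for cat in ("local", "global"):
        evs = [e for e in stage.population_events if e.category == cat]
        for name in _ALIGN_EVENTS:
            if name not in trials.columns:
                continue
            frac = bh.align_burst_fraction(
                evs, trials.set_index("trial")[name], cfg.alignment_window
            )
            align_rows.append(
                {"align_event": name, "category": cat, "fraction": frac}
            )
        occ = bh.burst_occupancy_vs_trial_time(evs, trials)
        occ["category"] = cat
        occ_rows.append(occ)
    return pd.DataFrame(align_rows), pd.concat(occ_rows, ignore_index=True)


def recovery_stage(
    session_trials: list[pd.DataFrame], cfg: PipelineConfig
) -> pd.DataFrame | None:
    """Recovery table treating the first session as the pre-stroke baseline.

    Returns None when no baseline deficit exists (synthetic sessions are
    statistically stationary, so this is the common case) or with fewer
    than two sessions.
    """
    if len(session_trials) < 2:
        return None
    session_trials = [
        df[np.isfinite(df["reach_start"])].reset_index(drop=True)
        for df in session_trials
    ]
    if any(len(df) == 0 for df in session_trials):
        warnings.warn("recovery table skipped: a session has no analyzable trials")
        return None
    base = session_trials[0]
    tt = bh.trial_times(base, cfg.trial_timeout)
    base = base.assign(trial_time=[tt[t] for t in base["trial"]])
    prestroke = base.groupby("slot")["trial_time"].mean().to_dict()
    daily = {
        df["session"].iloc[0] if "session" in df else str(i): df
        for i, df in enumerate(session_trials[1:], start=1)
    }
    try:
        return bh.recovery_index(
            daily, prestroke, cfg.trial_timeout, cfg.early_late_threshold
        )
    except ValueError as err:
        warnings.warn(f"recovery table skipped: {err}")
        return None


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(
        {k: str(v) for k, v in cfg.__dict__.items()}, sort_keys=True
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    cfg: PipelineConfig,
    session_paths: list[str],
    out_dir: str,
    bundles: list[SessionBundle] | None = None,
) -> dict:
    """Run every stage over the sessions and write a results directory.

    Returns the manifest dict. With an empty session list, writes an empty
    manifest and warns.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "n_sessions": len(session_paths) if bundles is None else len(bundles),
        "stages": {},
        "status": "ok",
    }
    if bundles is None:
        bundles = [read_session(p) for p in session_paths]
    if not bundles:
        warnings.warn("empty session list; nothing to do")
        manifest["status"] = "empty"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest

    stages = [detect_stage(b, cfg) for b in bundles]
    manifest["stages"]["detect"] = {
        b.session_id: len(st.channel_events) for b, st in zip(bundles, stages)
    }
    fit = classify_stage(stages, cfg)
    with open(out / "threshold.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "frac_thresh_global_local": float(fit.threshold),
                "weights": [float(w) for w in fit.weights],
                "means": [float(m) for m in fit.means],
                "sds": [float(s) for s in fit.sds],
                "collapsed": bool(fit.collapsed),
                "n_days": fit.n_days,
            },
            fh,
        )
    manifest["stages"]["classify"] = {
        st.bundle.session_id: {
            "global": sum(e.category == "global" for e in st.population_events),
            "local": sum(e.category == "local" for e in st.population_events),
        }
        for st in stages
    }

    burst_tables, pop_tables, spatial_tables = [], [], []
    cooc_rows, behavior_tables, firing_tables, entrain_tables = [], [], [], []
    speed_rows, align_tables, occupancy_tables, dynamics_tables = [], [], [], []
    for st in stages:
        sid = st.bundle.session_id
        burst_tables.append(bd.events_to_frame(st.channel_events, sid))
        pop_tables.append(bc.events_to_frame(st.population_events, sid))
        cooc = bc.subcortical_cooccurrence(st.population_events, st.sub_masks)
        cooc_rows.append({"session": sid, **cooc})

        geometry = st.bundle.geometry[st.included]
        for cat in ("local", "global"):
            evs = [e for e in st.population_events if e.category == cat]
            if not evs:
                continue
            if not st.included.all():
                evs = [
                    bc.PopulationBurstEvent(
                        e.category, e.start, e.end, e.start_idx, e.stop_idx,
                        e.fracact[st.included],
                    )
                    for e in evs
                ]
            summary = ss.clustering_statistic(
                evs, st.masks[st.included], geometry,
                n_shuffles=cfg.n_shuffles, seed=cfg.seed,
                session=sid, epoch_class=cat,
            )
            spatial_tables.append(ss.summary_to_frame(summary))

        trials = behavior_stage(st, cfg)
        trials.insert(0, "session", sid)
        behavior_tables.append(trials)

        reach_ep, grasp_ep = bh.define_epochs(trials, cfg.trial_timeout)
        kin = st.bundle.kinematics
        speed = bh.hand_speed(bh.smooth_positions(kin.position), kin.frame_times)
        by_cat = bh.speed_by_burst_category(
            speed, kin.frame_times, st.labels, st.fs,
            list(reach_ep.values()) + list(grasp_ep.values()),
        )
        for name, vals in by_cat.items():
            speed_rows.append(
                {
                    "session": sid,
                    "category": name,
                    "mean_speed": float(vals.mean()) if len(vals) else float("nan"),
                    "n_frames": len(vals),
                }
            )

        spk = spike_stage(st, trials, cfg)
        if len(spk["firing"]):
            spk["firing"].insert(0, "session", sid)
            firing_tables.append(spk["firing"])
        if len(spk["entrainment"]):
            spk["entrainment"].insert(0, "session", sid)
            entrain_tables.append(spk["entrainment"])

        align, occ = behavior_summary_stage(st, trials, cfg)
        align.insert(0, "session", sid)
        occ.insert(0, "session", sid)
        align_tables.append(align)
        occupancy_tables.append(occ)

        dyn = dynamics_stage(st, trials, cfg)
        if dyn is not None:
            dyn.insert(0, "session", sid)
            dynamics_tables.append(dyn)

    def _dump(tables, name):
        if tables:
            write_tsv(pd.concat(tables, ignore_index=True), str(out / name))

    _dump(burst_tables, "channel_bursts.tsv")
    _dump(pop_tables, "population_events.tsv")
    _dump(spatial_tables, "spatial_stats.tsv")
    _dump(behavior_tables, "trials.tsv")
    _dump(firing_tables, "burst_conditioned_firing.tsv")
    _dump(entrain_tables, "entrainment.tsv")
    _dump(align_tables, "alignment_fractions.tsv")
    _dump(occupancy_tables, "burst_occupancy.tsv")
    _dump(dynamics_tables, "dynamics_r2.tsv")
    recovery = recovery_stage(behavior_tables, cfg)
    if recovery is not None:
        write_tsv(recovery, str(out / "recovery.tsv"))
    write_tsv(pd.DataFrame(cooc_rows), str(out / "subcortical_cooccurrence.tsv"))
    write_tsv(pd.DataFrame(speed_rows), str(out / "speed_by_category.tsv"))
    manifest["threshold"] = float(fit.threshold)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    cfg.to_yaml(str(out / "config.yaml"))
    return manifest
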