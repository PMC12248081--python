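# betaburst

Detection and classification of **global vs. local beta bursts** in
multichannel cortical + subcortical field potentials, together with the
downstream analyses that characterise the two burst classes: spatial
clustering on the electrode grid, spike–phase entrainment with a shuffle
null, burst-conditioned firing statistics, one-step linear
population-dynamics predictability, and reach-to-grasp behavioral metrics
(kinematic event extraction, recovery index, burst–behavior alignment).

Because no public recordings ship with this package, a first-class
synthetic-session generator (`betaburst.synthetic_data`) produces
ground-truthed HDF5 session bundles with the statistical structure the
analyses assume: pink-noise LFP with injected narrow-band bursts of two
classes (array-wide, high-amplitude, long, lower-frequency "global" events
that usually coincide with subcortical bursting; spatially clustered,
lower-amplitude, shorter "local" events), von Mises phase-coupled Poisson
spike trains with rate suppression during global events, and bell-shaped
reach kinematics that slow down inside global bursts.

## Method summary

1. **Preprocess** (`lfp_preprocess`): anti-aliased decimation (default
   factor 3), zero-phase Butterworth band-pass in an animal-specific beta
   band (default 15–35 Hz, order 3), Hilbert analytic amplitude and phase;
   Welch PSDs from 4 s windows with 1 s overlap.
2. **Detect** (`burst_detect`): per channel per session, a burst is a
   maximal run of envelope samples above the envelope **median** that lasts
   ≥ 100 ms and whose maximum reaches **median + SD**. Features: normalized
   amplitude `(mean − median)/SD`, duration, and mean instantaneous
   frequency `dphase·fs/2π`.
3. **Classify** (`burst_classify`): per sample, the fraction of cortical
   channels bursting; a two-Gaussian mixture fitted to the day-averaged
   fraction distribution gives one threshold for all days (its crossing
   point between the component means). Samples are labelled 0/1/2
   (none/local/global; ≥ 3 channels required for either burst label), and
   label-pure runs ≥ 100 ms become population burst events. Subcortical
   co-occurrence is the fraction of in-event samples with ≥ 1 subcortical
   channel bursting.
4. **Spatial statistics** (`spatial_stats`): per event, the
   activity-weighted centroid of bursting channels and the weighted mean
   distance to it, calibrated against a column-shuffle null (100 shuffles)
   that conserves the column multiset exactly.
5. **Spikes** (`spike_analysis`): unit inclusion (waveform SNR > 3, rate
   > 0.5 Hz), 10 ms-binned rate and rate-SD by burst condition, resultant
   vector length of in-burst spike phases per unit × channel with a
   100-draw rate-matched shuffle null (significant if above the 95th
   percentile; modulation z-score), entrainment–rate association tables,
   and an `X_t = A X_{t−1}` dynamics model (50 ms bins, random trial/unit
   subsampling × 200) with per-trial per-category R².
6. **Behavior** (`behavior`): reach/grasp starts from smoothed hand speed
   (Gaussian kernel 11 frames / SD 1 frame, crossing-frame peak search
   ± 200 ms, 0.1 × peak-speed rule), normalized durations, percent correct,
   a 0–1 recovery index, ±0.35 s burst–event alignment fractions, burst
   occupancy vs. trial time, and speed by burst category.

## CLI

```sh
# generate a synthetic session bundle (HDF5 + ground-truth TSVs)
betaburst simulate --config synth.yaml --out day0.h5 --seed 1

# run the full pipeline over one or more sessions
betaburst run --config pipeline.yaml --sessions day0.h5 --sessions day1.h5 --out results/

# summarise a results directory
betaburst report results/
```

`betaburst run` writes deterministic TSV tables (`channel_bursts.tsv`,
`population_events.tsv`, `spatial_stats.tsv`, `trials.tsv`,
`subcortical_cooccurrence.tsv`, `speed_by_category.tsv`,
`burst_conditioned_firing.tsv`, `entrainment.tsv`,
`alignment_fractions.tsv`, `burst_occupancy.tsv`, `dynamics_r2.tsv`, and —
when a baseline deficit exists — `recovery.tsv` with the first session as
the pre-stroke baseline), the fitted threshold (`threshold.yaml`), the
effective config, and a run manifest (`manifest.json`). Both YAML configs
are optional; all defaults are the analysis constants above.

## Layout

```
src/betaburst/
  config.py          # SynthConfig / BurstClassParams / PipelineConfig
  io.py              # SessionBundle, GroundTruth, HDF5 + TSV round trips
  synthetic_data.py  # ground-truthed session generator
  lfp_preprocess.py  # decimation, PSD, analytic beta signal
  burst_detect.py    # dual-threshold per-channel burst detection
  burst_classify.py  # fraction series, mixture threshold, 0/1/2 labels
  spatial_stats.py   # burst centers, distances, column-shuffle null
  spike_analysis.py  # SNR, firing stats, entrainment, dynamics model
  behavior.py        # kinematic events, recovery index, burst-behavior
  pipeline.py        # orchestration, TSV outputs, manifest
  cli.py             # click entry points
```
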