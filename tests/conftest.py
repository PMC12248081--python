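import pytest

from betaburst.config import SynthConfig


def small_config(seed: int = 0, duration: float = 120.0) -> SynthConfig:
    """A fast-to-generate session used by module-level tests."""
    cfg = SynthConfig(
        seed=seed,
        session_duration=duration,
        fs_raw=600.0,
        n_units=8,
        n_subcortical_channels=16,
    )
    return cfg


@pytest.fixture(scope="session")
def small_session():
    """One generated small session shared across module tests."""
    from betaburst.synthetic_data import generate_session

    cfg = small_config(seed=11)
    bundle, truth = generate_session(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def small_processed(small_session):
    """Detection products (decimated analytic signal, events, masks)."""
    from betaburst import burst_detect as bd
    from betaburst import lfp_preprocess as lp

    cfg, bundle, truth = small_session
    dec, fs = lp.decimate_lfp(bundle.lfp_cortex, bundle.fs, 2)
    ab = lp.analytic_beta(dec, cfg.beta_band, fs, 3)
    thr = bd.compute_channel_thresholds(ab.amplitude)
    events = bd.detect_channel_bursts(ab.amplitude, thr, fs, phase=ab.phase)
    masks = bd.burst_masks(events, bundle.n_cortical_channels, dec.shape[1])
    return {
        "cfg": cfg,
        "bundle": bundle,
        "truth": truth,
        "fs": fs,
        "analytic": ab,
        "thresholds": thr,
        "events": events,
        "masks": masks,
    }


def naive_burst_scan(env, thresh, thresh2, fs, min_duration=0.100):
    """Independent per-sample reference scan for burst spans (oracle)."""
    spans = []
    n = len(env)
    i = 0
    while i < n:
        if env[i] > thresh:
            j = i
            while j < n and env[j] > thresh:
                j += 1
            run = env[i:j]
            if (j - i) / fs >= min_duration - 1e-12 and max(run) >= thresh2:
                spans.append((i, j))
            i = j
        else:
            i += 1
    return spans


def overlap_matched(true_start, true_end, detected, min_frac=0.5):
    """True event matched if some detected span overlaps >= min_frac of it."""
    need = min_frac * (true_end - true_start)
    return any(min(true_end, e) - max(true_start, s) >= need for s, e in detected)
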