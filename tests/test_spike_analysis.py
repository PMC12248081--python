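import numpy as np
import pytest
from scipy import stats
from scipy.special import i0, i1

from betaburst.spike_analysis import (
    bin_condition_labels,
    binned_rates,
    burst_conditioned_firing,
    category_predictability,
    entrainment_rate_association,
    epoch_firing_stats,
    fit_dynamics_model,
    fit_linear_dynamics,
    heldout_r2,
    intersect_spans_with_epochs,
    make_unit_records,
    phase_entrainment,
    predict_one_step,
    resultant_length,
    unit_snr,
)


class TestUnitSNR:
    def test_flat_waveform(self):
        assert unit_snr(np.zeros(30), (10, 20)) == 0.0

    def test_constructed_value(self):
        wf = np.zeros(40)
        wf[18] = -3.0
        wf[22] = 1.0  # peak - trough = 4
        rng = np.random.default_rng(0)
        tail = rng.standard_normal(40) * 0
        wf = wf + tail
        # make the tail SD exactly 1 outside the exclusion window
        wf[:16] = np.array([1, -1] * 8)  # SD = 1
        wf[24:] = np.array([1, -1] * 8)
        out = unit_snr(wf, (16, 24))
        assert out == pytest.approx(4.0, abs=0.2)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            wf = rng.standard_normal(48)
            lo, hi = 12, 30
            ref = (wf.max() - wf.min()) / np.concatenate(
                [wf[:lo], wf[hi:]]
            ).std()
            assert unit_snr(wf, (lo, hi)) == pytest.approx(ref)

    def test_full_exclusion_raises(self):
        with pytest.raises(ValueError):
            unit_snr(np.ones(10), (0, 10))

    def test_inclusion_rule(self):
        # SNR > 3 and rate > 0.5 Hz required
        wf_good = np.zeros(40)
        wf_good[18], wf_good[22] = -5.0, 5.0
        wf_good[:12] = 0.1 * np.array([1, -1] * 6)
        spikes = {"a": np.linspace(0, 99, 200), "b": np.linspace(0, 99, 10)}
        waveforms = {"a": (wf_good, None), "b": (wf_good, None)}
        recs = make_unit_records(spikes, waveforms, 100.0)
        by = {r.unit: r for r in recs}
        assert by["a"].included  # 2 Hz
        assert not by["b"].included  # 0.1 Hz


class TestEpochFiring:
    def test_one_spike_per_bin(self):
        spikes = np.arange(0.005, 1.0, 0.010)
        out = epoch_firing_stats(spikes, [(0.0, 1.0)])
        assert out.mean_rate == pytest.approx(100.0)
        assert out.variability == pytest.approx(0.0)

    def test_no_spikes(self):
        out = epoch_firing_stats(np.array([]), [(0.0, 1.0)])
        assert out.mean_rate == 0.0
        assert out.variability == 0.0

    def test_poisson_rate_recovered(self):
        rng = np.random.default_rng(2)
        lam = 20.0
        epochs = [(i * 10.0, i * 10.0 + 5.0) for i in range(40)]
        spikes = np.sort(rng.uniform(0, 400, rng.poisson(lam * 400)))
        out = epoch_firing_stats(spikes, epochs)
        se = np.sqrt(lam / (0.01 * 500 * 40)) * 3
        assert out.mean_rate == pytest.approx(lam, abs=5 * se + 1.0)

    def test_short_epoch_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            out = epoch_firing_stats(np.array([0.5]), [(0.0, 0.005), (0.0, 1.0)])
        assert out.n_trials == 1

    def test_empty_epochs_raise(self):
        with pytest.raises(ValueError):
            epoch_firing_stats(np.array([1.0]), [])


class TestBurstConditioned:
    def test_tie_goes_to_lower_code(self):
        fs = 100.0
        labels = np.zeros(100, dtype=np.int8)
        labels[0:5] = 2  # half of the first 10-sample bin (50 ms at fs=100? no)
        # bin 0.05 s = 5 samples; first bin = samples 0..4 all label 2
        out = bin_condition_labels(labels, fs, 0.0, 2, 0.05)
        assert out[0] == 2 and out[1] == 0
        labels2 = np.zeros(10, dtype=np.int8)
        labels2[0:5] = 1
        out2 = bin_condition_labels(labels2, fs, 0.0, 1, 0.10)
        assert out2[0] == 0  # 5 vs 5 tie -> lower code

    def test_all_zero_labels_reduce_to_epoch_stats(self):
        rng = np.random.default_rng(3)
        spikes = np.sort(rng.uniform(0, 50, 400))
        labels = np.zeros(5000, dtype=np.int8)
        epochs = [(5.0, 10.0), (20.0, 30.0)]
        cond = burst_conditioned_firing(spikes, labels, 100.0, epochs)
        base = epoch_firing_stats(spikes, epochs)
        assert cond["none"].mean_rate == pytest.approx(base.mean_rate)
        assert cond["none"].variability == pytest.approx(base.variability)
        assert cond["local"].n_trials == 0
        assert cond["global"].n_trials == 0

    def test_label_independent_spikes_show_no_difference(self):
        rng = np.random.default_rng(4)
        n_units = 40
        labels = np.zeros(60_000, dtype=np.int8)  # 600 s at 100 Hz
        # random label-2 stretches
        for _ in range(300):
            s = rng.integers(0, 59_000)
            labels[s: s + rng.integers(20, 60)] = 2
        epochs = [(i * 10.0, i * 10.0 + 8.0) for i in range(60)]
        diffs = []
        for _ in range(n_units):
            spikes = np.sort(rng.uniform(0, 600, rng.poisson(8 * 600)))
            cond = burst_conditioned_firing(spikes, labels, 100.0, epochs)
            diffs.append(cond["global"].mean_rate - cond["none"].mean_rate)
        diffs = np.array(diffs)
        assert abs(diffs.mean()) < 2 * diffs.std(ddof=1) / np.sqrt(n_units)


class TestEntrainment:
    def test_identical_phases_r1(self):
        assert resultant_length(np.full(100, 1.3)) == pytest.approx(1.0)

    def test_symmetric_phases_r0(self):
        r = resultant_length(np.array([0, np.pi / 2, np.pi, 3 * np.pi / 2]))
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        ph = rng.vonmises(0.5, 1.2, 500)
        r0 = resultant_length(ph)
        assert resultant_length(ph + 1.9) == pytest.approx(r0)

    def test_von_mises_bessel_ratio(self):
        # oracle: closed form I1(k)/I0(k); 0.446 at kappa=1
        rng = np.random.default_rng(6)
        kappa = 1.0
        ph = rng.vonmises(0.0, kappa, 10_000)
        expected = i1(kappa) / i0(kappa)
        assert expected == pytest.approx(0.446, abs=0.001)
        assert resultant_length(ph) == pytest.approx(expected, abs=0.01)

    def test_machinery_matches_direct_resultant(self):
        rng = np.random.default_rng(7)
        n = 4000
        phase = rng.vonmises(0.0, 1.0, n)[None, :]
        spikes = np.arange(n) / 1000.0
        res = phase_entrainment(spikes, phase, 1000.0, [(0, n)], seed=0)
        assert res.n_spikes == n
        assert res.r[0] == pytest.approx(resultant_length(phase[0]))
        assert res.defined

    def test_zero_spikes_flagged(self):
        phase = np.zeros((2, 100))
        res = phase_entrainment(np.array([]), phase, 100.0, [(0, 100)])
        assert not res.defined
        assert res.n_spikes == 0
        assert np.isnan(res.r).all()
        assert not res.significant.any()

    def test_no_events_raise(self):
        with pytest.raises(ValueError):
            phase_entrainment(np.array([0.5]), np.zeros((1, 100)), 100.0, [])

    def test_intersect_spans(self):
        out = intersect_spans_with_epochs([(0, 100), (150, 300)],
                                          [(0.5, 2.0)], 100.0)
        assert out == [(50, 100), (150, 200)]


class TestAssociation:
    def _results(self, zs, sig=True):
        from betaburst.spike_analysis import EntrainmentResult

        out = {}
        for u, z in zs.items():
            n_ch = 4
            out[u] = EntrainmentResult(
                n_spikes=50,
                r=np.full(n_ch, 0.5),
                shuffle_mean=np.full(n_ch, 0.2),
                shuffle_sd=np.full(n_ch, 0.1),
                shuffle_p95=np.full(n_ch, 0.4 if sig else 0.9),
                z=np.full(n_ch, z),
                significant=np.full(n_ch, sig),
                defined=True,
            )
        return out

    def test_unit_without_significant_channels_excluded(self):
        res = self._results({"a": 2.0}, sig=False)
        table, _ = entrainment_rate_association(res, {"a": (-1.0, -1.0)})
        assert len(table) == 0

    def test_planted_negative_slope(self):
        rng = np.random.default_rng(8)
        zs = {f"u{i}": float(z) for i, z in enumerate(np.linspace(0.5, 5, 30))}
        deltas = {u: (-0.8 * z + rng.normal(0, 0.3), -0.5 * z)
                  for u, z in zs.items()}
        table, summary = entrainment_rate_association(self._results(zs), deltas)
        assert len(table) == 30
        assert summary["delta_rate"]["slope"] < 0
        assert summary["delta_rate"]["p"] < 0.01

    def test_shuffled_labels_slope_ci_covers_zero(self):
        rng = np.random.default_rng(9)
        zs = {f"u{i}": float(rng.uniform(0.5, 5)) for i in range(40)}
        deltas = {u: (float(rng.normal(0, 1)), float(rng.normal(0, 1)))
                  for u in zs}
        _, summary = entrainment_rate_association(self._results(zs), deltas)
        assert summary["delta_rate"]["p"] > 0.01


def _random_stable_A(n, rng, radius=0.9):
    A = rng.standard_normal((n, n))
    A *= radius / np.max(np.abs(np.linalg.eigvals(A)))
    return A


def _simulate_trials(A, n_trials, n_bins, rng, noise=0.0):
    n = A.shape[0]
    trials = []
    for _ in range(n_trials):
        x = np.empty((n, n_bins))
        x[:, 0] = rng.standard_normal(n)
        for t in range(1, n_bins):
            x[:, t] = A @ x[:, t - 1] + noise * rng.standard_normal(n)
        trials.append(x)
    return trials


class TestDynamics:
    def test_exact_recovery_noiseless(self):
        rng = np.random.default_rng(10)
        A = _random_stable_A(6, rng)
        trials = _simulate_trials(A, 6, 60, rng)
        A_hat = fit_linear_dynamics(trials[:4])
        assert np.allclose(A_hat, A, atol=1e-8)
        assert heldout_r2(A_hat, trials[4:]) == pytest.approx(1.0, abs=1e-10)

    def test_white_data_no_predictability(self):
        rng = np.random.default_rng(11)
        trials = [rng.standard_normal((6, 300)) for _ in range(4)]
        A_hat = fit_linear_dynamics(trials[:2])
        assert heldout_r2(A_hat, trials[2:]) <= 0.05

    def test_noise_r2_closed_form(self):
        # oracle: R^2 ~= 1 - sigma^2 / total variance of the true bins
        rng = np.random.default_rng(12)
        A = _random_stable_A(5, rng, radius=0.95)
        sigma = 0.4
        trials = _simulate_trials(A, 12, 200, rng, noise=sigma)
        A_hat = fit_linear_dynamics(trials[:6])
        held = trials[6:]
        true = np.concatenate([tr[:, 1:] for tr in held], axis=1)
        total_var = np.mean(
            (true - true.mean(axis=1, keepdims=True)) ** 2
        )
        expected = 1.0 - sigma**2 / total_var
        assert heldout_r2(A_hat, held) == pytest.approx(expected, abs=0.05)

    def test_unit_order_invariance(self):
        rng = np.random.default_rng(13)
        A = _random_stable_A(5, rng)
        trials = _simulate_trials(A, 4, 80, rng, noise=0.2)
        perm = rng.permutation(5)
        A1 = fit_linear_dynamics(trials[:2])
        A2 = fit_linear_dynamics([t[perm] for t in trials[:2]])
        assert np.allclose(A2, A1[np.ix_(perm, perm)], atol=1e-8)
        r1 = heldout_r2(A1, trials[2:])
        r2 = heldout_r2(A2, [t[perm] for t in trials[2:]])
        assert r1 == pytest.approx(r2)

    def test_subsampling_reps(self):
        rng = np.random.default_rng(14)
        A = _random_stable_A(8, rng)
        trials = _simulate_trials(A, 12, 50, rng, noise=0.3)
        models = fit_dynamics_model(trials, n_train_trials=8, n_units=5,
                                    n_reps=10, seed=0)
        assert len(models) == 10
        for m in models:
            assert m.A.shape == (5, 5)
            assert len(m.train_trials) == 8
        # determinism
        models2 = fit_dynamics_model(trials, 8, 5, n_reps=10, seed=0)
        assert np.allclose(models[3].A, models2[3].A)

    def test_insufficient_data_raises(self):
        rng = np.random.default_rng(15)
        trials = [rng.standard_normal((4, 20)) for _ in range(5)]
        with pytest.raises(ValueError):
            fit_dynamics_model(trials, n_train_trials=8, n_units=2)
        with pytest.raises(ValueError):
            fit_dynamics_model(trials, n_train_trials=2, n_units=12)

    def test_binned_rates(self):
        spikes = [np.array([0.01, 0.06, 0.07]), np.array([0.12])]
        out = binned_rates(spikes, (0.0, 0.15), bin_s=0.05)
        assert out.shape == (2, 3)
        assert np.allclose(out[0], [20.0, 40.0, 0.0])
        assert np.allclose(out[1], [0.0, 0.0, 20.0])


class TestCategoryPredictability:
    def test_perfect_prediction(self):
        rng = np.random.default_rng(16)
        true = rng.standard_normal((4, 30))
        labels = rng.integers(0, 3, 30).astype(np.int8)
        out = category_predictability(true, true.copy(), labels)
        for v in out.values():
            assert v == pytest.approx(1.0)

    def test_mean_prediction_gives_zero(self):
        rng = np.random.default_rng(17)
        true = rng.standard_normal((3, 40))
        labels = np.zeros(40, dtype=np.int8)
        pred = np.repeat(true.mean(axis=1, keepdims=True), 40, axis=1)
        out = category_predictability(true, pred, labels)
        assert out["none"] == pytest.approx(0.0, abs=1e-12)

    def test_min_bins(self):
        true = np.random.default_rng(18).standard_normal((2, 10))
        labels = np.zeros(10, dtype=np.int8)
        labels[0] = 2  # single global bin < min_bins
        out = category_predictability(true, true, labels, min_bins=2)
        assert np.isnan(out["global"])

    def test_zero_variance_flagged(self):
        true = np.ones((2, 10))
        labels = np.zeros(10, dtype=np.int8)
        out = category_predictability(true, true, labels)
        assert np.isnan(out["none"])

    def test_planted_global_perturbation(self):
        # dynamics perturbed only inside global bins -> global R^2 < none
        rng = np.random.default_rng(19)
        A = _random_stable_A(6, rng, radius=0.95)
        n_trials, n_bins = 60, 80
        worse = 0
        valid = 0
        for _ in range(n_trials):
            x = np.empty((6, n_bins))
            x[:, 0] = rng.standard_normal(6)
            labels = np.zeros(n_bins, dtype=np.int8)
            s = rng.integers(10, 40)
            labels[s: s + 20] = 2
            for t in range(1, n_bins):
                noise = 1.0 if labels[t] == 2 else 0.1
                x[:, t] = A @ x[:, t - 1] + noise * rng.standard_normal(6)
            pred = predict_one_step(A, x)
            out = category_predictability(x[:, 1:], pred, labels[1:])
            if np.isfinite(out["global"]) and np.isfinite(out["none"]):
                valid += 1
                worse += out["global"] < out["none"]
        assert valid >= 50
        p = stats.binomtest(worse, valid, 0.5, alternative="greater").pvalue
        assert p < 0.01
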