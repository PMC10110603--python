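"""Spike/discharge rules, artifact rejection, relative band powers."""

import numpy as np
import pandas as pd
import pytest

from chloropatch.eeg import (BandPowerTransformer, Discharge,
                             EpileptiformSpikeDetector, detect_spikes,
                             discharge_rate, group_discharges,
                             relative_band_powers)
from chloropatch.synth import (EEGGroundTruth, SynthConfig,
                               eeg_spike_template, gen_eeg)
from chloropatch.trace import EEGRecording, Trace


def brute_force_discharges(times, min_spikes=3, max_interval=0.2):
    """Independent O(n²) enumeration of maximal qualifying runs."""
    times = list(times)
    out = []
    i = 0
    while i < len(times):
        j = i
        while j + 1 < len(times) and times[j + 1] - times[j] <= max_interval:
            j += 1
        if j - i + 1 >= min_spikes:
            out.append(tuple(times[i:j + 1]))
        i = j + 1
    return out


def recording_with_baseline(x, fs=2000.0, baseline=(0.0, 15.0)):
    ann = pd.DataFrame([{"start_s": baseline[0], "end_s": baseline[1],
                         "label": "nonrem"}])
    return EEGRecording(Trace(x, fs, "uV"), ann)


class TestDischargeGrouping:
    def test_worked_example(self):
        d = group_discharges([0.0, 0.1, 0.25, 1.0, 1.15, 2.0])
        assert len(d) == 1
        assert d[0].n_spikes == 3
        assert d[0].spike_times_s == (0.0, 0.1, 0.25)

    def test_fewer_than_three_spikes_empty(self):
        assert group_discharges([0.0, 0.1]) == []

    def test_oracle_equivalence_on_random_trains(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            times = np.sort(rng.uniform(0, 60, 500))
            got = [d.spike_times_s for d in group_discharges(times)]
            expected = brute_force_discharges(times)
            assert got == expected

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            group_discharges([1.0, 0.5, 2.0])

    def test_window_mode_is_stricter(self):
        # three spikes with pairwise ISIs of 150 ms span 300 ms: a run
        # under the ISI reading, not under the single-window reading
        times = [0.0, 0.15, 0.30]
        assert len(group_discharges(times, mode="isi")) == 1
        assert group_discharges(times, mode="window") == []


class TestDischargeRate:
    def test_zero_discharges(self):
        assert discharge_rate([], 3600.0)["rate_per_hour"] == 0.0

    def test_rate_arithmetic(self):
        d = [Discharge((0.0,), 0.0, 0.0, 3)] * 12
        r = discharge_rate(d, 24 * 3600.0)
        assert r["rate_per_hour"] == pytest.approx(0.5)
        assert r["count"] == 12


class TestSpikeDetection:
    def test_flat_recording_has_no_spikes(self):
        rec = recording_with_baseline(np.zeros(int(2000 * 60)))
        assert len(detect_spikes(rec)) == 0

    def test_planted_spikes_recovered(self):
        rng = np.random.default_rng(3)
        spike_times = np.arange(20.0, 110.0, 1.8)
        cfg = SynthConfig(seed=11, sampling_rate=2000, duration=120,
                          noise_sd=30.0)
        gt = EEGGroundTruth(spike_times=tuple(spike_times),
                            band_mix=(0.4, 0.3, 0.2, 0.1),
                            baseline_interval=(0.0, 18.0))
        rec, _ = gen_eeg(cfg, gt)
        det = EpileptiformSpikeDetector().fit(rec)
        dt = det.spikes_["time_s"].to_numpy()
        matched = sum(np.min(np.abs(dt - t)) < 0.05 for t in spike_times)
        false = sum(np.min(np.abs(spike_times - t)) > 0.05 for t in dt)
        assert matched / spike_times.size >= 0.95
        assert false <= 2

    def test_slow_wave_rejected_by_duration_rule(self):
        # 400-ms flat-topped wave at 10×SD must yield zero spikes
        fs = 2000.0
        rng = np.random.default_rng(2)
        x = rng.normal(0, 10, int(fs * 60))
        sd = x[:int(15 * fs)].std()
        from scipy.signal import windows
        wave = -10 * sd * windows.tukey(int(0.4 * fs), alpha=0.3)
        x[int(30 * fs):int(30 * fs) + wave.size] += wave
        rec = recording_with_baseline(x)
        spikes = detect_spikes(rec)
        assert not ((spikes["time_s"] > 29.9) & (spikes["time_s"] < 30.6)).any()

    def test_duration_rule_on_noiseless_input(self):
        # noiseless: a planted >200 ms artifact is always rejected and a
        # planted <100 ms spike is always kept
        fs = 2000.0
        x = np.zeros(int(fs * 60))
        x[:int(15 * fs)] = np.sin(np.arange(int(15 * fs)) * 0.37)  # baseline
        tmpl = eeg_spike_template(fs, amplitude=20.0)
        x[int(30 * fs):int(30 * fs) + tmpl.size] += tmpl
        from scipy.signal import windows
        x[int(40 * fs):int(40 * fs) + int(0.4 * fs)] += \
            -20.0 * windows.tukey(int(0.4 * fs), alpha=0.3)
        rec = recording_with_baseline(x)
        spikes = detect_spikes(rec)
        in_spike = ((spikes["time_s"] > 29.9) & (spikes["time_s"] < 30.3))
        in_artifact = ((spikes["time_s"] > 39.9) & (spikes["time_s"] < 40.6))
        assert in_spike.sum() == 1
        assert in_artifact.sum() == 0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 10, int(2000 * 120))
        tmpl = eeg_spike_template(2000.0, amplitude=60.0)
        for t0 in np.arange(20, 110, 2.0):
            i = int(t0 * 2000)
            x[i:i + tmpl.size] += tmpl
        rec = recording_with_baseline(x)
        counts = [len(detect_spikes(
            rec, params=__import__("chloropatch.eeg", fromlist=["x"])
            .SpikeDetectionParams(threshold_multiplier=k)))
            for k in (2.0, 4.0, 6.0, 10.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_missing_baseline_annotation_is_an_error(self):
        rec = EEGRecording(Trace(np.zeros(2000 * 30), 2000.0, "uV"))
        with pytest.raises(ValueError, match="baseline"):
            EpileptiformSpikeDetector().fit(rec)


class TestBandPowers:
    def test_pure_tone_concentrates_in_theta(self):
        fs = 2000.0
        t = np.arange(int(9 * fs)) / fs
        rec = EEGRecording(Trace(50 * np.sin(2 * np.pi * 6 * t), fs, "uV"))
        bp = relative_band_powers(rec, [(0.0, 9.0)])
        assert bp.relative["theta"] >= 0.99

    def test_white_noise_matches_bandwidth_fractions(self):
        rng = np.random.default_rng(5)
        fs = 2000.0
        rec = EEGRecording(Trace(rng.normal(0, 1, int(fs * 105)), fs, "uV"))
        epochs = [(2.0 + 10 * i, 11.0 + 10 * i) for i in range(10)]
        bp = relative_band_powers(rec, epochs)
        expected = {"delta": 3 / 29, "theta": 5 / 29, "alpha": 4 / 29,
                    "beta": 17 / 29}
        for band, frac in expected.items():
            assert bp.relative[band] == pytest.approx(frac, abs=0.02)

    def test_normalization_sums_to_one_per_epoch(self):
        rng = np.random.default_rng(6)
        fs = 2000.0
        rec = EEGRecording(Trace(rng.normal(0, 1, int(fs * 50)), fs, "uV"))
        bp = relative_band_powers(rec, [(1.0, 10.0), (12.0, 21.0)])
        sums = bp.per_epoch[[f"rel_{b}" for b in
                             ("delta", "theta", "alpha", "beta")]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_generated_band_mix_recovered(self):
        mix = (0.4, 0.3, 0.2, 0.1)
        cfg = SynthConfig(seed=0, sampling_rate=2000, duration=105,
                          noise_sd=25.0)
        rec, _ = gen_eeg(cfg, EEGGroundTruth(band_mix=mix))
        epochs = [(2.0 + 10 * i, 11.0 + 10 * i) for i in range(10)]
        bp = relative_band_powers(rec, epochs)
        for band, target in zip(("delta", "theta", "alpha", "beta"), mix):
            assert bp.relative[band] == pytest.approx(target, abs=0.03)

    def test_artifact_epochs_rejected_with_warning(self):
        rng = np.random.default_rng(7)
        fs = 2000.0
        ann = pd.DataFrame([{"start_s": 12.0, "end_s": 13.0,
                             "label": "artifact"}])
        rec = EEGRecording(Trace(rng.normal(0, 1, int(fs * 40)), fs, "uV"),
                           ann)
        with pytest.warns(UserWarning, match="artifact"):
            bp = relative_band_powers(rec, [(1.0, 10.0), (11.0, 20.0)])
        assert bp.n_epochs == 1

    def test_all_epochs_rejected_is_an_error(self):
        rng = np.random.default_rng(8)
        fs = 2000.0
        ann = pd.DataFrame([{"start_s": 0.0, "end_s": 30.0,
                             "label": "artifact"}])
        rec = EEGRecording(Trace(rng.normal(0, 1, int(fs * 30)), fs, "uV"),
                           ann)
        with pytest.raises(ValueError, match="rejected"), \
                pytest.warns(UserWarning):
            relative_band_powers(rec, [(1.0, 10.0)])

    def test_wrong_epoch_length_rejected(self):
        rng = np.random.default_rng(9)
        rec = EEGRecording(Trace(rng.normal(0, 1, 2000 * 30), 2000.0, "uV"))
        with pytest.raises(ValueError, match="9"):
            relative_band_powers(rec, [(0.0, 5.0)])

    def test_transformer_is_sklearn_compatible(self):
        tf = BandPowerTransformer()
        assert tf.get_params()["epoch_duration_s"] == 9.0
        tf.set_params(welch_window_s=4.0)
        assert tf.welch_window_s == 4.0
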