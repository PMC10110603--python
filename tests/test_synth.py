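"""Generators: determinism, ground-truth conservation, circuit physics."""

import numpy as np
import pytest
from scipy import optimize, signal as sps
from scipy.stats import poisson

from chloropatch.synth import (BAND_EDGES, ClampGroundTruth, EEGGroundTruth,
                               SynthConfig, biexp_template, gen_eeg,
                               gen_iv_protocol, gen_mini_trace,
                               gen_tonic_trace)


def circuit_peak_oracle(v_com, gt):
    """Independent brute-force solve of the series-resistance circuit.

    Finds the clamp current with the GABA conductance fully open and at
    rest by root-finding the implicit loop equation, rather than the
    closed form the generator uses.
    """
    def solve(g_gaba):
        def loop(i):
            v_m = v_com - 1e-3 * gt.true_rs * i
            return (gt.leak_conductance * (v_m - gt.e_leak)
                    + g_gaba * (v_m - gt.true_e_rev)) - i
        return optimize.brentq(loop, -1e7, 1e7)

    i_rest = solve(0.0)
    i_peak = solve(gt.gaba_peak_conductance)
    return i_peak - i_rest, i_peak


class TestIVProtocol:
    def test_zero_driving_force_gives_zero_peak(self):
        cfg = SynthConfig(seed=1, duration=0.5)
        gt = ClampGroundTruth(true_e_rev=-70.0, true_rs=0.0,
                              command_schedule=(-80.0, -70.0, -60.0))
        traces, _ = gen_iv_protocol(cfg, gt)
        trace = traces[-70.0]
        baseline = trace.samples[:100].mean()
        assert np.max(np.abs(trace.samples - baseline)) < 1e-9

    def test_same_seed_reproduces_samples_exactly(self):
        cfg = SynthConfig(seed=7, duration=0.3, noise_sd=4.0)
        gt = ClampGroundTruth()
        t1, _ = gen_iv_protocol(cfg, gt)
        t2, _ = gen_iv_protocol(cfg, gt)
        for v in gt.command_schedule:
            np.testing.assert_array_equal(t1[v].samples, t2[v].samples)

    def test_peak_currents_match_circuit_solve_oracle(self):
        # series resistance shifts the apparent zero crossing; every
        # per-step peak must agree with an independent root-finder
        cfg = SynthConfig(seed=1, duration=0.5)
        gt = ClampGroundTruth(true_e_rev=-70.0, true_rs=10.0,
                              leak_conductance=20.0)
        traces, _ = gen_iv_protocol(cfg, gt)
        for v in gt.command_schedule:
            delta_oracle, _ = circuit_peak_oracle(v, gt)
            trace = traces[v]
            baseline = trace.samples[:1000].mean()
            delta = trace.samples - baseline
            peak = delta[np.argmax(np.abs(delta))]
            assert peak == pytest.approx(delta_oracle, rel=1e-6, abs=1e-9)

    def test_zero_rs_peak_linear_in_driving_force(self):
        cfg = SynthConfig(seed=1, duration=0.5)
        gt = ClampGroundTruth(true_e_rev=-70.0, true_rs=0.0)
        traces, _ = gen_iv_protocol(cfg, gt)
        peaks = {}
        for v in gt.command_schedule:
            delta = traces[v].samples - traces[v].samples[:1000].mean()
            peaks[v] = delta[np.argmax(np.abs(delta))]
        for v, p in peaks.items():
            expected = gt.gaba_peak_conductance * (v - gt.true_e_rev)
            assert p == pytest.approx(expected, rel=1e-6, abs=1e-9)

    def test_schedule_not_spanning_reversal_refused(self):
        cfg = SynthConfig(seed=1, duration=0.5)
        gt = ClampGroundTruth(true_e_rev=-30.0,
                              command_schedule=(-80.0, -70.0, -60.0))
        with pytest.raises(ValueError, match="span"):
            gen_iv_protocol(cfg, gt)

    def test_too_few_distinct_potentials_refused(self):
        gt = ClampGroundTruth(command_schedule=(-80.0, -80.0, -60.0))
        with pytest.raises(ValueError, match="distinct"):
            gen_iv_protocol(SynthConfig(seed=1, duration=0.5), gt)


class TestMiniTrace:
    def test_zero_rate_gives_pure_noise_and_empty_truth(self):
        cfg = SynthConfig(seed=3, duration=20.0, noise_sd=2.0)
        trace, truth = gen_mini_trace(cfg, rate=0.0)
        assert truth.size == 0
        assert abs(trace.samples.std() - 2.0) < 0.1

    def test_event_count_within_poisson_99_interval(self):
        cfg = SynthConfig(seed=11, duration=300.0)
        _, truth = gen_mini_trace(cfg, rate=5.0)
        lo, hi = poisson.ppf(0.005, 1500), poisson.ppf(0.995, 1500)
        assert lo <= truth.size <= hi

    def test_single_noiseless_event_has_planted_amplitude(self):
        cfg = SynthConfig(seed=5, duration=10.0)
        trace, truth = gen_mini_trace(cfg, rate=0.2, amp_mean=20.0)
        assert truth.size > 0
        assert np.max(np.abs(trace.samples)) == pytest.approx(20.0, rel=1e-6)

    def test_truth_sorted_and_deterministic(self):
        cfg = SynthConfig(seed=4, duration=60.0, noise_sd=1.0)
        t1, e1 = gen_mini_trace(cfg, rate=3.0)
        t2, e2 = gen_mini_trace(cfg, rate=3.0)
        np.testing.assert_array_equal(t1.samples, t2.samples)
        np.testing.assert_array_equal(e1, e2)
        assert np.all(np.diff(e1) >= 0)

    def test_invalid_kinetics_rejected(self):
        cfg = SynthConfig(seed=1, duration=20.0)
        with pytest.raises(ValueError, match="kinetics"):
            gen_mini_trace(cfg, rate=1.0, rise_ms=8.0, decay_ms=2.0)

    def test_biexp_template_unit_peak(self):
        t = np.arange(-0.01, 0.2, 1e-5)
        y = biexp_template(t, 2.0, 8.0)
        assert y.max() == pytest.approx(1.0, abs=1e-6)
        assert np.all(y[t < 0] == 0)


class TestTonicTrace:
    def test_zero_shift_keeps_baseline_flat(self):
        cfg = SynthConfig(seed=2, duration=60.0)
        trace, _ = gen_tonic_trace(cfg, tonic_shift=0.0,
                                   antagonist_onset=30.0)
        pre = trace.window(0, 25).mean()
        post = trace.window(40, 55).mean()
        assert post - pre == pytest.approx(0.0, abs=1e-12)

    def test_planted_shift_appears_after_settling(self):
        cfg = SynthConfig(seed=2, duration=60.0)
        trace, truth = gen_tonic_trace(cfg, tonic_shift=20.0,
                                       antagonist_onset=20.0)
        pre = trace.window(10, 19).mean()
        post = trace.window(45, 59).mean()
        assert post - pre == pytest.approx(20.0, abs=1e-9)
        assert truth["tonic_shift"] == 20.0

    def test_minis_suppressed_after_onset(self):
        cfg = SynthConfig(seed=6, duration=60.0)
        _, truth = gen_tonic_trace(cfg, tonic_shift=10.0,
                                   antagonist_onset=30.0, mini_rate=3.0)
        assert np.all(truth["mini_times"] < 30.0)

    def test_onset_outside_trace_rejected(self):
        cfg = SynthConfig(seed=1, duration=10.0)
        with pytest.raises(ValueError, match="onset"):
            gen_tonic_trace(cfg, tonic_shift=5.0, antagonist_onset=15.0)


class TestEEG:
    def test_planted_spike_count_conserved(self):
        times = tuple(np.linspace(5, 85, 50))
        cfg = SynthConfig(seed=8, sampling_rate=2000, duration=90,
                          noise_sd=20.0)
        rec, gt = gen_eeg(cfg, EEGGroundTruth(spike_times=times))
        assert len(gt.spike_times) == 50
        assert rec.signal.n_samples == 90 * 2000

    def test_same_seed_identical_recording(self):
        cfg = SynthConfig(seed=13, sampling_rate=2000, duration=30,
                          noise_sd=20.0)
        r1, _ = gen_eeg(cfg, EEGGroundTruth())
        r2, _ = gen_eeg(cfg, EEGGroundTruth())
        np.testing.assert_array_equal(r1.signal.samples, r2.signal.samples)

    def test_spectral_contract_matches_band_mix(self):
        # high-resolution periodogram oracle, independent of the
        # epoch-based analyzer
        mix = (0.4, 0.3, 0.2, 0.1)
        cfg = SynthConfig(seed=0, sampling_rate=2000, duration=95,
                          noise_sd=25.0)
        rec, _ = gen_eeg(cfg, EEGGroundTruth(band_mix=mix))
        f, psd = sps.periodogram(rec.signal.samples, fs=2000)
        powers = np.array([psd[(f >= lo) & (f < hi)].sum()
                           for lo, hi in BAND_EDGES.values()])
        rel = powers / powers.sum()
        np.testing.assert_allclose(rel, mix, atol=0.02)

    def test_band_mix_normalized_with_warning(self):
        cfg = SynthConfig(seed=1, sampling_rate=2000, duration=10,
                          noise_sd=10.0)
        with pytest.warns(UserWarning, match="normaliz"):
            gen_eeg(cfg, EEGGroundTruth(band_mix=(2.0, 1.0, 1.0, 1.0)))

    def test_spike_inside_artifact_rejected(self):
        cfg = SynthConfig(seed=1, sampling_rate=2000, duration=30,
                          noise_sd=10.0)
        gt = EEGGroundTruth(spike_times=(10.0,),
                            artifact_intervals=((9.5, 10.5),))
        with pytest.raises(ValueError, match="artifact"):
            gen_eeg(cfg, gt)

    def test_short_artifact_interval_rejected(self):
        gt = EEGGroundTruth(artifact_intervals=((5.0, 5.1),))
        cfg = SynthConfig(seed=1, sampling_rate=2000, duration=30,
                          noise_sd=10.0)
        with pytest.raises(ValueError, match="200 ms"):
            gen_eeg(cfg, gt)
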