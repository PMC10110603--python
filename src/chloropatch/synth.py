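"""Seeded synthetic-data generators with attached ground truth.

Every input the analysis pipeline consumes can be generated here with the
true underlying parameters returned alongside, so each downstream stage is
testable against known answers without any recorded data:

* :func:`gen_iv_protocol` — GABA-evoked currents at stepped command
  potentials through a series-resistance voltage divider;
* :func:`gen_mini_trace` — Poisson trains of bi-exponential miniature
  postsynaptic currents in Gaussian noise;
* :func:`gen_tonic_trace` — an antagonist-induced tonic baseline shift
  with superimposed minis before antagonist onset;
* :func:`gen_eeg` — band-mixture EEG background with planted epileptiform
  spikes (< 200 ms) and slow artifacts (> 200 ms).

All generators draw from substreams derived from one root seed, so each
generator is byte-reproducible independently of the others.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .trace import EEGRecording, Trace

__all__ = [
    "SynthConfig", "ClampGroundTruth", "EEGGroundTruth",
    "gen_iv_protocol", "gen_mini_trace", "gen_tonic_trace", "gen_eeg",
    "biexp_template", "eeg_spike_template", "BAND_NAMES",
]

BAND_NAMES = ("delta", "theta", "alpha", "beta")


@dataclass
class SynthConfig:
    """Common generator settings.

    noise_sd is in the units of the generated signal: pA for clamp
    traces, µV for EEG.
    """

    seed: int = 0
    sampling_rate: float = 10_000.0
    duration: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _rng(cfg: SynthConfig, label: str) -> np.random.Generator:
    """Substream derived from the root seed and a generator label."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed,
                               spawn_key=(zlib.crc32(label.encode()),)))


@dataclass
class ClampGroundTruth:
    """True circuit parameters behind a synthetic I–V protocol.

    Conductances are in nS, potentials in mV, series resistance in MΩ;
    with these units nS·mV = pA and pA·MΩ = µV (handled explicitly).
    """

    true_e_rev: float = -70.0
    true_rs: float = 0.0
    leak_conductance: float = 5.0
    gaba_peak_conductance: float = 10.0
    command_schedule: tuple[float, ...] = (-100., -90., -80., -70., -60., -50., -40.)
    e_leak: float = -65.0

    def validate(self) -> None:
        distinct = sorted(set(self.command_schedule))
        if len(distinct) < 3:
            raise ValueError("command_schedule needs >= 3 distinct potentials")
        if not (distinct[0] <= self.true_e_rev <= distinct[-1]):
            raise ValueError(
                "command schedule does not span the reversal potential; "
                "the reversal would be unidentifiable")
        if self.true_rs < 0:
            raise ValueError("series resistance must be non-negative")


def biexp_template(t: np.ndarray, rise_ms: float, decay_ms: float) -> np.ndarray:
    """Difference-of-exponentials transient normalized to unit peak.

    ``(exp(-t/τ_d) - exp(-t/τ_r))`` for t ≥ 0, zero before, scaled so the
    maximum equals 1. Requires decay_ms > rise_ms > 0.
    """
    if rise_ms <= 0 or decay_ms <= rise_ms:
        raise ValueError("invalid kinetics: need decay_ms > rise_ms > 0")
    tr, td = rise_ms / 1000.0, decay_ms / 1000.0
    t = np.asarray(t, dtype=float)
    shape = np.where(t >= 0, np.exp(-np.maximum(t, 0) / td)
                     - np.exp(-np.maximum(t, 0) / tr), 0.0)
    t_peak = tr * td / (td - tr) * np.log(td / tr)
    peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    return shape / peak


def _clamp_current(v_com: float, g_gaba: np.ndarray,
                   gt: ClampGroundTruth) -> np.ndarray:
    """Closed-form clamp current for the series-resistance divider.

    Solves I = g_L(V_m − E_L) + g_G(V_m − E_G) with V_m = V_com − I·Rs
    (pA·MΩ = 10⁻³ mV) self-consistently at each sample.
    """
    g_l = gt.leak_conductance
    g_tot = g_l + g_gaba
    num = g_tot * v_com - g_l * gt.e_leak - g_gaba * gt.true_e_rev
    return num / (1.0 + 1e-3 * gt.true_rs * g_tot)


def gen_iv_protocol(cfg: SynthConfig, gt: ClampGroundTruth,
                    stim_time: float = 0.2, rise_ms: float = 2.0,
                    decay_ms: float = 30.0,
                    ) -> tuple[dict[float, Trace], ClampGroundTruth]:
    """GABA-response traces at each command potential of the schedule.

    Each trace is leak current plus a transient GABA conductance whose
    driving force is (V_m − E_rev), with V_m distorted by the
    series-resistance voltage drop; Gaussian noise of ``cfg.noise_sd``
    is added. Returns ``{V_com: Trace}`` and the unchanged ground truth.
    """
    gt.validate()
    if not stim_time < cfg.duration:
        raise ValueError("stim_time must fall inside the trace")
    rng = _rng(cfg, "iv")
    n = int(round(cfg.duration * cfg.sampling_rate))
    t = np.arange(n) / cfg.sampling_rate
    g_gaba = gt.gaba_peak_conductance * biexp_template(
        t - stim_time, rise_ms, decay_ms)
    traces: dict[float, Trace] = {}
    for v_com in gt.command_schedule:
        current = _clamp_current(v_com, g_gaba, gt)
        if cfg.noise_sd > 0:
            current = current + rng.normal(0.0, cfg.noise_sd, size=n)
        traces[v_com] = Trace(current, cfg.sampling_rate, units="pA")
    return traces, gt


def _poisson_times(rng: np.random.Generator, rate: float,
                   duration: float) -> np.ndarray:
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def _insert_transients(samples: np.ndarray, fs: float, times: np.ndarray,
                       amps: np.ndarray, rise_ms: float, decay_ms: float,
                       sign: float) -> None:
    """Add amp·template at each onset time, in place."""
    span = int(round((rise_ms + 8 * decay_ms) / 1000.0 * fs)) + 1
    t_local = np.arange(span) / fs
    template = biexp_template(t_local, rise_ms, decay_ms)
    for t0, amp in zip(times, amps):
        i0 = int(round(t0 * fs))
        i1 = min(i0 + span, samples.size)
        if i1 > i0:
            samples[i0:i1] += sign * amp * template[: i1 - i0]


def gen_mini_trace(cfg: SynthConfig, rate: float, amp_mean: float = 20.0,
                   rise_ms: float = 2.0, decay_ms: float = 8.0,
                   amp_cv: float = 0.0, polarity: str = "inward",
                   ) -> tuple[Trace, np.ndarray]:
    """Homogeneous-Poisson miniature PSC train in Gaussian noise.

    Returns the trace and the true event onset times, sorted ascending.
    ``polarity="inward"`` plants negative deflections (the convention for
    mIPSCs recorded with a high-chloride pipette at −60 mV).
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if decay_ms <= rise_ms:
        raise ValueError("invalid kinetics: need decay_ms > rise_ms")
    sign = -1.0 if polarity == "inward" else 1.0
    rng = _rng(cfg, "minis")
    n = int(round(cfg.duration * cfg.sampling_rate))
    samples = np.zeros(n)
    times = _poisson_times(rng, rate, cfg.duration)
    amps = amp_mean * np.ones(times.size)
    if amp_cv > 0:
        sigma2 = np.log1p(amp_cv ** 2)
        amps *= rng.lognormal(-0.5 * sigma2, np.sqrt(sigma2), times.size)
    _insert_transients(samples, cfg.sampling_rate, times, amps,
                       rise_ms, decay_ms, sign)
    if cfg.noise_sd > 0:
        samples += rng.normal(0.0, cfg.noise_sd, size=n)
    return Trace(samples, cfg.sampling_rate, units="pA"), times


def gen_tonic_trace(cfg: SynthConfig, tonic_shift: float,
                    antagonist_onset: float, mini_rate: float = 0.0,
                    holding_pa: float = -30.0, settle_tau: float = 0.5,
                    mini_amp: float = 20.0, mini_rise_ms: float = 2.0,
                    mini_decay_ms: float = 8.0,
                    ) -> tuple[Trace, dict]:
    """Baseline current with an antagonist-induced tonic shift.

    Before ``antagonist_onset`` the holding current sits at
    ``holding_pa`` (inward-negative, including the tonic GABA_A
    component) with minis superimposed; after onset the baseline relaxes
    by ``tonic_shift`` toward 0 pA with first-order settling
    (``settle_tau`` seconds) and minis are suppressed, emulating GABA_A
    blockade.
    """
    if not 0 < antagonist_onset < cfg.duration:
        raise ValueError("antagonist_onset must lie inside the trace")
    rng = _rng(cfg, "tonic")
    n = int(round(cfg.duration * cfg.sampling_rate))
    t = np.arange(n) / cfg.sampling_rate
    samples = np.full(n, float(holding_pa))
    post = t >= antagonist_onset
    samples[post] += tonic_shift * (
        1.0 - np.exp(-(t[post] - antagonist_onset) / settle_tau))
    mini_times = _poisson_times(rng, mini_rate, antagonist_onset)
    _insert_transients(samples, cfg.sampling_rate, mini_times,
                       mini_amp * np.ones(mini_times.size),
                       mini_rise_ms, mini_decay_ms, sign=-1.0)
    if cfg.noise_sd > 0:
        samples += rng.normal(0.0, cfg.noise_sd, size=n)
    truth = {"tonic_shift": tonic_shift, "antagonist_onset": antagonist_onset,
             "holding_pa": holding_pa, "settle_tau": settle_tau,
             "mini_times": mini_times}
    return Trace(samples, cfg.sampling_rate, units="pA"), truth


@dataclass
class EEGGroundTruth:
    """Planted content of a synthetic EEG record.

    band_mix gives the target relative powers of (δ, θ, α, β); it is
    normalized (with a warning) if it does not sum to 1. artifact
    intervals must each exceed 200 ms; planted spikes must not fall
    inside artifact intervals.
    """

    spike_times: tuple[float, ...] = ()
    spike_amplitudes: tuple[float, ...] = ()
    artifact_intervals: tuple[tuple[float, float], ...] = ()
    band_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    baseline_interval: tuple[float, float] | None = None
    artifact_amplitude: float | None = None

    def validate(self, duration: float) -> None:
        if len(self.spike_amplitudes) not in (0, len(self.spike_times)):
            raise ValueError("spike_amplitudes must match spike_times")
        for t in self.spike_times:
            if not 0 <= t <= duration:
                raise ValueError("spike time outside record")
            for a, b in self.artifact_intervals:
                if a <= t <= b:
                    raise ValueError("planted spike inside artifact interval")
        for a, b in self.artifact_intervals:
            if b - a <= 0.2:
                raise ValueError("artifact intervals must exceed 200 ms")
            if a < 0 or b > duration:
                raise ValueError("artifact interval outside record")


# Band edges in Hz: δ 1–4, θ 4–9, α 9–13, β 13–30.
BAND_EDGES = {"delta": (1.0, 4.0), "theta": (4.0, 9.0),
              "alpha": (9.0, 13.0), "beta": (13.0, 30.0)}


def eeg_spike_template(fs: float, amplitude: float,
                       neg_sigma_ms: float = 8.0, pos_frac: float = 0.5,
                       pos_sigma_ms: float = 10.0,
                       lobe_gap_ms: float = 25.0) -> np.ndarray:
    """Biphasic epileptiform spike: sharp negative then positive lobe.

    Total width ~60–80 ms, safely under the 200-ms artifact-rejection
    bound; ``amplitude`` sets the negative-lobe peak magnitude in µV.
    """
    half = int(round(0.06 * fs))
    t = (np.arange(2 * half + 1) - half) / fs * 1000.0  # ms
    neg = -np.exp(-0.5 * (t / neg_sigma_ms) ** 2)
    pos = pos_frac * np.exp(-0.5 * ((t - lobe_gap_ms) / pos_sigma_ms) ** 2)
    return amplitude * (neg + pos)


def gen_eeg(cfg: SynthConfig, gt: EEGGroundTruth,
            ) -> tuple[EEGRecording, EEGGroundTruth]:
    """Synthetic EEG: band-mixture background, planted spikes, artifacts.

    The background is a sum of band-limited Gaussian noises, one per
    band, each scaled so the relative powers over the four canonical
    bands match ``gt.band_mix``; total background SD is ``cfg.noise_sd``
    (µV). Spikes use :func:`eeg_spike_template`; artifacts are
    raised-cosine slow waves spanning each artifact interval.
    """
    if cfg.sampling_rate < 60.0:
        raise ValueError("sampling rate must cover the beta band (>= 60 Hz)")
    gt.validate(cfg.duration)
    mix = np.asarray(gt.band_mix, dtype=float)
    if mix.min() < 0:
        raise ValueError("band_mix entries must be non-negative")
    total = mix.sum()
    if not np.isclose(total, 1.0):
        warnings.warn("band_mix does not sum to 1; normalizing",
                      stacklevel=2)
        mix = mix / total
    rng = _rng(cfg, "eeg")
    n = int(round(cfg.duration * cfg.sampling_rate))
    background = np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / cfg.sampling_rate)
    for weight, band in zip(mix, BAND_NAMES):
        if weight == 0:
            continue
        lo, hi = BAND_EDGES[band]
        # brick-wall band-limited noise: all component power lies inside
        # its nominal band, so the analyzed relative powers track the
        # requested mix without filter-skirt leakage
        spec = np.fft.rfft(rng.normal(0.0, 1.0, size=n))
        spec[(freqs < lo) | (freqs >= hi)] = 0.0
        comp = np.fft.irfft(spec, n=n)
        comp /= comp.std()
        background += np.sqrt(weight) * comp
    if cfg.noise_sd > 0:
        background *= cfg.noise_sd / max(background.std(), 1e-30)
    samples = background
    amps = gt.spike_amplitudes or tuple(
        8.0 * cfg.noise_sd for _ in gt.spike_times)
    for t0, amp in zip(gt.spike_times, amps):
        template = eeg_spike_template(cfg.sampling_rate, amp)
        i0 = int(round(t0 * cfg.sampling_rate)) - template.size // 2
        lo_i, hi_i = max(i0, 0), min(i0 + template.size, n)
        samples[lo_i:hi_i] += template[lo_i - i0: hi_i - i0]
    art_amp = gt.artifact_amplitude
    if art_amp is None:
        art_amp = 10.0 * (cfg.noise_sd if cfg.noise_sd > 0 else 1.0)
    for a, b in gt.artifact_intervals:
        i0, i1 = int(round(a * cfg.sampling_rate)), int(round(b * cfg.sampling_rate))
        i1 = min(i1, n)
        # flat-topped slow wave: the supra-threshold excursion spans
        # essentially the whole planted interval, exercising the
        # duration-based artifact rejection unambiguously
        samples[i0:i1] += -art_amp * sps.windows.tukey(i1 - i0, alpha=0.3)
    rows = [{"start_s": a, "end_s": b, "label": "artifact"}
            for a, b in gt.artifact_intervals]
    if gt.baseline_interval is not None:
        a, b = gt.baseline_interval
        rows.append({"start_s": a, "end_s": b, "label": "nonrem"})
    annotations = pd.DataFrame(rows, columns=["start_s", "end_s", "label"])
    rec = EEGRecording(Trace(samples, cfg.sampling_rate, units="uV"),
                       annotations)
    return rec, gt
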