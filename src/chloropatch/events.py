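"""Miniature postsynaptic current detection, kinetics, and paired-pulse ratio.

Minis are detected by an amplitude threshold expressed in multiples of
the robust noise SD (median absolute deviation), replacing by automation
what is classically done by eye in a GUI. Each event is characterized by
its peak amplitude, 10–90% rise time and a monoexponential decay time
constant; events whose decay fit does not converge are kept for
frequency counts but excluded from kinetic averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal as sps
from scipy.ndimage import uniform_filter1d
from sklearn.base import BaseEstimator

from .trace import Trace

__all__ = [
    "MiniEvent", "MiniSummary", "MiniEventDetector", "detect_minis",
    "characterize_event", "summarize_minis", "paired_pulse_ratio",
    "robust_noise_sd", "ClippedTraceError",
]


class ClippedTraceError(ValueError):
    """Raised when a trace looks saturated/clipped at the ADC rails."""


@dataclass
class MiniEvent:
    """One detected miniature PSC.

    ``amplitude_pa`` is the positive magnitude of the peak relative to
    the local pre-event baseline; polarity is carried separately.
    ``decay_tau_ms`` is a monoexponential time constant fitted from the
    peak; ``fit_ok`` is False when that fit failed to converge (the
    event still counts toward frequency).
    """

    onset_s: float
    peak_time_s: float
    amplitude_pa: float
    polarity: str
    rise_10_90_ms: float | None = None
    decay_tau_ms: float | None = None
    fit_ok: bool = True


@dataclass
class MiniSummary:
    """Per-cell mini statistics: frequency plus arithmetic means."""

    frequency: float
    frequency_unit: str
    mean_amplitude_pa: float | None
    mean_rise_ms: float | None
    mean_decay_ms: float | None
    n_events: int
    duration_s: float


def robust_noise_sd(x: np.ndarray) -> float:
    """Noise SD via 1.4826·MAD — insensitive to sparse events."""
    x = np.asarray(x, dtype=float)
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def _check_not_clipped(x: np.ndarray) -> None:
    # A healthy analog signal almost never sits repeatedly at its exact
    # extremes; long flat runs at min/max indicate saturation.
    n = x.size
    if n < 100:
        return
    med = np.median(x)
    at_rail = 0
    if x.max() > med:  # a flat baseline sitting at the median is normal
        at_rail += int((x == x.max()).sum())
    if x.min() < med:
        at_rail += int((x == x.min()).sum())
    if at_rail > max(10, n // 1000):
        raise ClippedTraceError(
            f"{at_rail} samples pinned at the trace extremes; "
            "recording looks saturated/clipped")


class MiniEventDetector(BaseEstimator):
    """Threshold detector for miniature postsynaptic currents.

    Parameters
    ----------
    polarity : {"inward", "outward"}
        Direction of the synaptic deflection; inward (negative) for
        mIPSCs recorded with a high-chloride pipette.
    threshold_multiplier : float
        Detection threshold in multiples of the robust noise SD.
    refractory_ms : float
        Minimum separation between detected peaks; closer candidates
        are merged.
    decay_fit_ms : float
        Length of the post-peak segment used for the decay fit.

    Attributes
    ----------
    noise_sd_ : float
    threshold_pa_ : float
    events_ : list of MiniEvent
    """

    def __init__(self, polarity: str = "inward",
                 threshold_multiplier: float = 3.5,
                 refractory_ms: float = 5.0,
                 smooth_ms: float = 1.0,
                 baseline_ms: float = 5.0,
                 decay_fit_ms: float = 40.0,
                 min_duration_s: float = 10.0):
        self.polarity = polarity
        self.threshold_multiplier = threshold_multiplier
        self.refractory_ms = refractory_ms
        self.smooth_ms = smooth_ms
        self.baseline_ms = baseline_ms
        self.decay_fit_ms = decay_fit_ms
        self.min_duration_s = min_duration_s

    def fit(self, X: Trace, y=None):
        """Detect and characterize events on a trace."""
        trace = X
        if trace.duration < self.min_duration_s:
            raise ValueError(
                f"trace shorter than {self.min_duration_s} s; noise SD "
                "cannot be estimated reliably")
        if self.polarity not in ("inward", "outward"):
            raise ValueError("polarity must be 'inward' or 'outward'")
        _check_not_clipped(trace.samples)
        fs = trace.sampling_rate
        sign = -1.0 if self.polarity == "inward" else 1.0
        samples = trace.samples
        if self.smooth_ms > 0:
            w = max(int(round(self.smooth_ms / 1000.0 * fs)), 1)
            if w > 1:
                samples = uniform_filter1d(samples, size=w, mode="nearest")
        s = sign * (samples - np.median(samples))
        self.noise_sd_ = robust_noise_sd(s)
        self.threshold_pa_ = self.threshold_multiplier * self.noise_sd_
        distance = max(int(round(self.refractory_ms / 1000.0 * fs)), 1)
        # prominence gate: secondary noise maxima riding an event's decay
        # clear the height threshold but have only noise-sized prominence
        peaks, _ = sps.find_peaks(
            s, height=self.threshold_pa_, distance=distance,
            prominence=self.threshold_pa_ if self.threshold_pa_ > 0 else None)
        smoothed = Trace(samples, fs, trace.units, trace.t0)
        margin = int(round(0.002 * fs))
        self.events_ = [
            characterize_event(smoothed, peak_idx=int(p),
                               polarity=self.polarity,
                               baseline_ms=self.baseline_ms,
                               decay_fit_ms=self.decay_fit_ms,
                               end_idx=(int(peaks[k + 1]) - margin
                                        if k + 1 < peaks.size else None))
            for k, p in enumerate(peaks)]
        self.n_events_ = len(self.events_)
        return self

    def transform(self, X: Trace) -> pd.DataFrame:
        """Detect on ``X`` and return a per-event DataFrame."""
        self.fit(X)
        return pd.DataFrame(
            [{"onset_s": e.onset_s, "amplitude_pA": e.amplitude_pa,
              "rise_ms": e.rise_10_90_ms, "decay_ms": e.decay_tau_ms,
              "fit_ok": e.fit_ok} for e in self.events_])


def detect_minis(trace: Trace, polarity: str = "inward",
                 threshold_multiplier: float = 3.5,
                 **kwargs) -> list[MiniEvent]:
    """Detected events sorted by onset; see :class:`MiniEventDetector`."""
    det = MiniEventDetector(polarity=polarity,
                            threshold_multiplier=threshold_multiplier,
                            **kwargs)
    det.fit(trace)
    return det.events_


def characterize_event(trace: Trace, peak_idx: int | None = None,
                       onset_s: float | None = None,
                       polarity: str = "inward", baseline_ms: float = 5.0,
                       decay_fit_ms: float = 40.0,
                       search_ms: float = 15.0,
                       end_idx: int | None = None) -> MiniEvent:
    """Amplitude, 10–90% rise time and decay constant of one event.

    The event may be located either by its peak sample index or by an
    approximate onset time (the peak is then searched within
    ``search_ms`` after the onset). The local baseline is the mean over
    ``baseline_ms`` just before the rising limb; the decay constant is a
    least-squares monoexponential fitted from the peak over
    ``decay_fit_ms``. A decay that cannot be fit (e.g. a step with no
    decay) flags the event instead of raising.
    """
    fs = trace.sampling_rate
    sign = -1.0 if polarity == "inward" else 1.0
    s = sign * trace.samples
    if peak_idx is None:
        if onset_s is None:
            raise ValueError("need peak_idx or onset_s")
        i0 = trace.index_at(onset_s)
        i1 = min(i0 + max(int(round(search_ms / 1000 * fs)), 2),
                 trace.n_samples)
        peak_idx = i0 + int(np.argmax(s[i0:i1]))
    n_base = max(int(round(baseline_ms / 1000 * fs)), 1)

    # walk back from the peak to the pre-event baseline: first sample
    # (searching backwards) at or below 10% of the provisional amplitude
    provisional_base = float(np.median(
        s[max(peak_idx - 10 * n_base, 0): max(peak_idx - n_base, 1)]))
    back_limit = max(peak_idx - int(round(0.030 * fs)), 0)
    rel = s[back_limit:peak_idx + 1] - provisional_base
    amp0 = rel[-1]
    onset_idx = back_limit
    below = np.nonzero(rel <= 0.1 * amp0)[0]
    if below.size:
        onset_idx = back_limit + below[-1]
    base_lo = max(onset_idx - n_base, 0)
    baseline = float(np.mean(s[base_lo:onset_idx])) if onset_idx > base_lo \
        else provisional_base
    amplitude = float(s[peak_idx] - baseline)

    rise = _rise_10_90_ms(s, onset_idx, peak_idx, baseline, amplitude, fs)
    tau, fit_ok = _decay_tau_ms(s, peak_idx, baseline, amplitude, fs,
                                decay_fit_ms, end_idx=end_idx)
    return MiniEvent(onset_s=trace.t0 + onset_idx / fs,
                     peak_time_s=trace.t0 + peak_idx / fs,
                     amplitude_pa=amplitude, polarity=polarity,
                     rise_10_90_ms=rise, decay_tau_ms=tau, fit_ok=fit_ok)


def _rise_10_90_ms(s, onset_idx, peak_idx, baseline, amplitude, fs):
    if peak_idx <= onset_idx or amplitude <= 0:
        return None
    seg = s[onset_idx:peak_idx + 1] - baseline
    t = np.arange(seg.size) / fs * 1000.0

    def crossing(frac):
        target = frac * amplitude
        above = np.nonzero(seg >= target)[0]
        if not above.size:
            return None
        j = above[0]
        if j == 0:
            return t[0]
        # linear interpolation between the bracketing samples
        f = (target - seg[j - 1]) / (seg[j] - seg[j - 1])
        return t[j - 1] + f * (t[j] - t[j - 1])

    t10, t90 = crossing(0.1), crossing(0.9)
    if t10 is None or t90 is None or t90 <= t10:
        return None
    return float(t90 - t10)


def _decay_tau_ms(s, peak_idx, baseline, amplitude, fs, decay_fit_ms,
                  end_idx=None, start_frac=0.5):
    n_fit = int(round(decay_fit_ms / 1000 * fs))
    stop = peak_idx + n_fit
    if end_idx is not None:
        stop = min(stop, end_idx)
    seg = s[peak_idx: stop] - baseline
    if seg.size < 5 or amplitude <= 0:
        return None, False
    # skip the near-peak plateau where the rise component still cancels
    # part of the decay: start where the falling limb drops below
    # start_frac of the amplitude
    below = np.nonzero(seg < start_frac * amplitude)[0]
    if below.size and seg.size - below[0] >= 5:
        seg = seg[below[0]:]
    t_ms = np.arange(seg.size) / fs * 1000.0

    def model(t, a, tau):
        return a * np.exp(-t / tau)

    try:
        popt, _ = optimize.curve_fit(
            model, t_ms, seg, p0=(amplitude, decay_fit_ms / 4),
            bounds=([0.0, 1e-3], [np.inf, 10 * decay_fit_ms]),
            maxfev=2000)
    except (RuntimeError, ValueError):
        return None, False
    tau = float(popt[1])
    # a "decay" slower than the whole fit window is indistinguishable
    # from a step — flag it rather than report a meaningless constant
    if tau >= 5 * decay_fit_ms or tau <= 0:
        return None, False
    return tau, True


def summarize_minis(events: list[MiniEvent], duration_s: float,
                    frequency_unit: str = "per_s") -> MiniSummary:
    """Frequency and arithmetic means over events.

    ``frequency_unit`` is ``"per_s"`` (mIPSC convention) or
    ``"per_min"`` (mEPSC convention). Kinetic means use only events with
    a converged decay fit; with zero events the kinetic means are absent
    and the frequency is 0.
    """
    if not duration_s > 0:
        raise ValueError("duration must be positive")
    if frequency_unit not in ("per_s", "per_min"):
        raise ValueError("frequency_unit must be 'per_s' or 'per_min'")
    n = len(events)
    freq = n / duration_s
    if frequency_unit == "per_min":
        freq *= 60.0
    if n == 0:
        return MiniSummary(0.0, frequency_unit, None, None, None, 0,
                           duration_s)
    good = [e for e in events if e.fit_ok]
    rises = [e.rise_10_90_ms for e in good if e.rise_10_90_ms is not None]
    decays = [e.decay_tau_ms for e in good if e.decay_tau_ms is not None]
    return MiniSummary(
        frequency=freq, frequency_unit=frequency_unit,
        mean_amplitude_pa=float(np.mean([e.amplitude_pa for e in events])),
        mean_rise_ms=float(np.mean(rises)) if rises else None,
        mean_decay_ms=float(np.mean(decays)) if decays else None,
        n_events=n, duration_s=duration_s)


def paired_pulse_ratio(trace: Trace, stim1_s: float, stim2_s: float,
                       artifact_blank_ms: float = 1.0,
                       response_ms: float = 45.0,
                       baseline_ms: float = 1.0) -> float:
    """Peak₂/peak₁ of two evoked responses (50-ms interval convention).

    Each peak is measured against a baseline taken just before its own
    stimulus; re-measuring the baseline before the second pulse
    subtracts the residual decay of the first response, so overlapping
    responses yield an unbiased ratio. The first ``artifact_blank_ms``
    after each stimulus is excluded from the peak search.
    """
    if stim2_s <= stim1_s:
        raise ValueError("second stimulus must follow the first")
    fs = trace.sampling_rate
    blank = artifact_blank_ms / 1000.0
    resp = response_ms / 1000.0
    base = baseline_ms / 1000.0

    def peak(stim, limit):
        b = float(np.mean(trace.window(stim - base, stim)))
        window_end = min(stim + resp, limit) if limit else stim + resp
        seg = trace.window(stim + blank, window_end)
        return float(seg[np.argmax(np.abs(seg - b))] - b)

    p1 = peak(stim1_s, stim2_s)
    p2 = peak(stim2_s, None)
    if p1 == 0:
        raise ValueError("first response peak is zero; PPR undefined")
    return p2 / p1
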