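"""Rule-based epileptiform spike/discharge detection and band powers.

Detection rules (all thresholds configurable, defaults as stated):

* threshold = 4 × SD of the baseline EEG during an annotated non-REM
  segment, applied to the rectified signal (either polarity);
* a candidate is a contiguous supra-threshold excursion; excursions
  longer than 200 ms are rejected as slow artifacts;
* three or more consecutive spikes with inter-spike intervals ≤ 200 ms
  form an epileptic discharge;
* discharge burden is reported as a rate per hour alongside the raw
  count and analyzed duration, so alternative normalizations can be
  recomputed.

Spectra use a segment-averaged (Welch) periodogram per 9-s awake epoch;
relative powers of δ (1–4), θ (4–9), α (9–13) and β (13–30 Hz) are
normalized by the sum over the four bands and averaged over epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .synth import BAND_EDGES
from .trace import EEGRecording

__all__ = [
    "SpikeDetectionParams", "Discharge", "BandPowerSummary",
    "EpileptiformSpikeDetector", "BandPowerTransformer",
    "detect_spikes", "group_discharges", "discharge_rate",
    "relative_band_powers",
]


@dataclass(frozen=True)
class SpikeDetectionParams:
    """Thresholds of the spike/discharge rules (defaults as in the text
    above)."""

    threshold_multiplier: float = 4.0
    max_waveform_duration_ms: float = 200.0
    min_spikes_per_discharge: int = 3
    max_within_discharge_interval_ms: float = 200.0
    merge_gap_ms: float = 10.0
    min_separation_ms: float = 40.0

    def __post_init__(self) -> None:
        for name in ("threshold_multiplier", "max_waveform_duration_ms",
                     "min_spikes_per_discharge",
                     "max_within_discharge_interval_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Discharge:
    """A grouped run of spikes counted as one epileptic discharge."""

    spike_times_s: tuple[float, ...]
    onset_s: float
    offset_s: float
    n_spikes: int


class EpileptiformSpikeDetector(BaseEstimator):
    """Amplitude-threshold spike detector with artifact rejection.

    The threshold is ``threshold_multiplier`` × SD of the signal inside
    the baseline interval (an annotated non-REM segment, or an explicit
    ``baseline_interval``). Supra-threshold excursions of the rectified
    signal separated by less than ``merge_gap_ms`` are bridged before
    the duration test, so noise dips inside one slow wave do not split
    it into spurious short events; accepted excursions closer than
    ``min_separation_ms`` are merged into a single spike (largest
    extremum wins).

    Attributes: ``baseline_sd_``, ``threshold_uv_``, ``spikes_``
    (DataFrame: time_s, amplitude, duration_ms), ``discharges_``,
    ``n_spikes_``.
    """

    def __init__(self, threshold_multiplier: float = 4.0,
                 max_waveform_duration_ms: float = 200.0,
                 min_spikes_per_discharge: int = 3,
                 max_within_discharge_interval_ms: float = 200.0,
                 merge_gap_ms: float = 10.0,
                 min_separation_ms: float = 40.0,
                 baseline_label: str = "nonrem",
                 min_baseline_s: float = 10.0):
        self.threshold_multiplier = threshold_multiplier
        self.max_waveform_duration_ms = max_waveform_duration_ms
        self.min_spikes_per_discharge = min_spikes_per_discharge
        self.max_within_discharge_interval_ms = max_within_discharge_interval_ms
        self.merge_gap_ms = merge_gap_ms
        self.min_separation_ms = min_separation_ms
        self.baseline_label = baseline_label
        self.min_baseline_s = min_baseline_s

    def fit(self, X: EEGRecording, y=None,
            baseline_interval: tuple[float, float] | None = None):
        rec = X
        fs = rec.sampling_rate
        if baseline_interval is None:
            intervals = rec.intervals(self.baseline_label)
            if not intervals:
                raise ValueError(
                    f"no '{self.baseline_label}' baseline annotation; the "
                    "detection threshold is anchored to a non-REM segment")
            baseline_interval = intervals[0]
        a, b = baseline_interval
        if b - a < self.min_baseline_s:
            raise ValueError(
                f"baseline interval shorter than {self.min_baseline_s} s")
        baseline = rec.signal.window(a, b)
        self.baseline_sd_ = float(baseline.std())
        self.threshold_uv_ = self.threshold_multiplier * self.baseline_sd_

        x = rec.signal.samples - float(np.median(rec.signal.samples))
        above = np.abs(x) > self.threshold_uv_
        runs = _contiguous_runs(above)
        runs = _bridge_gaps(runs, int(round(self.merge_gap_ms / 1000 * fs)))
        max_len = self.max_waveform_duration_ms / 1000.0 * fs
        spikes = []
        for i0, i1 in runs:
            if (i1 - i0) > max_len:
                continue  # slow waveform: artifact, rejected
            j = i0 + int(np.argmax(np.abs(x[i0:i1])))
            spikes.append((j, x[j], (i1 - i0) / fs * 1000.0))
        spikes = _merge_close(spikes,
                              int(round(self.min_separation_ms / 1000 * fs)))
        t0 = rec.signal.t0
        self.spikes_ = pd.DataFrame(
            [{"time_s": t0 + j / fs, "amplitude": amp, "duration_ms": dur}
             for j, amp, dur in spikes],
            columns=["time_s", "amplitude", "duration_ms"])
        self.n_spikes_ = len(self.spikes_)
        self.discharges_ = group_discharges(
            self.spikes_["time_s"].to_numpy(),
            min_spikes=self.min_spikes_per_discharge,
            max_interval_s=self.max_within_discharge_interval_ms / 1000.0)
        return self


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    stops = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def _bridge_gaps(runs: list[tuple[int, int]], max_gap: int
                 ) -> list[tuple[int, int]]:
    if not runs:
        return runs
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        if a - merged[-1][1] <= max_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def _merge_close(spikes: list[tuple[int, float, float]], min_sep: int
                 ) -> list[tuple[int, float, float]]:
    out: list[tuple[int, float, float]] = []
    for sp in spikes:
        if out and sp[0] - out[-1][0] < min_sep:
            if abs(sp[1]) > abs(out[-1][1]):
                out[-1] = sp
        else:
            out.append(sp)
    return out


def detect_spikes(rec: EEGRecording,
                  params: SpikeDetectionParams = SpikeDetectionParams(),
                  baseline_interval: tuple[float, float] | None = None,
                  ) -> pd.DataFrame:
    """Spike table (time_s, amplitude, duration_ms); see
    :class:`EpileptiformSpikeDetector`."""
    det = EpileptiformSpikeDetector(
        threshold_multiplier=params.threshold_multiplier,
        max_waveform_duration_ms=params.max_waveform_duration_ms,
        min_spikes_per_discharge=params.min_spikes_per_discharge,
        max_within_discharge_interval_ms=params.max_within_discharge_interval_ms,
        merge_gap_ms=params.merge_gap_ms,
        min_separation_ms=params.min_separation_ms)
    det.fit(rec, baseline_interval=baseline_interval)
    return det.spikes_


def group_discharges(spike_times_s, min_spikes: int = 3,
                     max_interval_s: float = 0.2,
                     mode: str = "isi") -> list[Discharge]:
    """Group spikes into discharges.

    ``mode="isi"`` (default): maximal runs in which every consecutive
    inter-spike interval is ≤ ``max_interval_s``; runs with at least
    ``min_spikes`` members become discharges. ``mode="window"`` instead
    requires each group of ``min_spikes`` consecutive spikes to fit
    inside a single ``max_interval_s`` window (the stricter alternative
    reading of the rule).
    """
    t = np.asarray(spike_times_s, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted ascending")
    if t.size < min_spikes:
        return []
    if mode == "isi":
        breaks = np.nonzero(np.diff(t) > max_interval_s)[0] + 1
        runs = np.split(t, breaks)
    elif mode == "window":
        ok = t[min_spikes - 1:] - t[: t.size - min_spikes + 1] \
            <= max_interval_s
        member = np.zeros(t.size, dtype=bool)
        for i in np.nonzero(ok)[0]:
            member[i: i + min_spikes] = True
        runs = [t[i0:i1] for i0, i1 in _contiguous_runs(member)]
    else:
        raise ValueError("mode must be 'isi' or 'window'")
    return [Discharge(spike_times_s=tuple(run), onset_s=float(run[0]),
                      offset_s=float(run[-1]), n_spikes=run.size)
            for run in runs if run.size >= min_spikes]


def discharge_rate(discharges: list[Discharge],
                   analyzed_duration_s: float) -> dict:
    """Discharges per hour, with the raw count and duration preserved."""
    if not analyzed_duration_s > 0:
        raise ValueError("analyzed duration must be positive")
    count = len(discharges)
    hours = analyzed_duration_s / 3600.0
    return {"count": count, "analyzed_duration_s": analyzed_duration_s,
            "rate_per_hour": count / hours}


@dataclass
class BandPowerSummary:
    """Per-epoch and epoch-averaged band powers.

    ``relative`` holds the mean over epochs of band power divided by the
    summed power of the four bands; the four values sum to 1.
    """

    per_epoch: pd.DataFrame
    relative: dict[str, float]
    absolute: dict[str, float]
    n_epochs: int
    epoch_duration_s: float
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(BAND_EDGES))


class BandPowerTransformer(TransformerMixin, BaseEstimator):
    """Welch-periodogram relative band powers over fixed-length epochs.

    Each epoch is analyzed with Hann-tapered ``welch_window_s`` segments
    at 50% overlap; band power integrates the PSD over half-open
    frequency intervals [lo, hi), so adjacent bands never share a bin.
    Epochs overlapping an annotated artifact are dropped with a warning.
    """

    def __init__(self, bands: dict[str, tuple[float, float]] | None = None,
                 epoch_duration_s: float = 9.0,
                 welch_window_s: float = 2.0,
                 artifact_label: str = "artifact"):
        self.bands = bands
        self.epoch_duration_s = epoch_duration_s
        self.welch_window_s = welch_window_s
        self.artifact_label = artifact_label

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: EEGRecording,
                  epochs: list[tuple[float, float]] | None = None,
                  ) -> BandPowerSummary:
        rec = X
        bands = self.bands or dict(BAND_EDGES)
        if epochs is None:
            epochs = rec.intervals("awake")
        if not epochs:
            raise ValueError("no epochs supplied or annotated as 'awake'")
        artifacts = rec.intervals(self.artifact_label)
        fs = rec.sampling_rate
        nperseg = int(round(self.welch_window_s * fs))
        rows = []
        for a, b in epochs:
            if abs((b - a) - self.epoch_duration_s) > 1.0 / fs:
                raise ValueError(
                    f"epoch [{a}, {b}] is not {self.epoch_duration_s} s")
            if any(a < art_b and b > art_a for art_a, art_b in artifacts):
                warnings.warn(f"epoch [{a}, {b}] overlaps an artifact; "
                              "rejected", stacklevel=2)
                continue
            seg = rec.signal.window(a, b)
            f, psd = sps.welch(seg, fs=fs, window="hann", nperseg=nperseg,
                               noverlap=nperseg // 2)
            row = {}
            for name, (lo, hi) in bands.items():
                # trapezoidal integral over the closed band; a PSD bin
                # sitting exactly on a shared edge contributes half to
                # each neighbor, so adjacent bands never double-count
                sel = (f >= lo) & (f <= hi)
                row[name] = float(np.trapezoid(psd[sel], f[sel]))
            rows.append({"start_s": a, "end_s": b, **row})
        if not rows:
            raise ValueError("every epoch was rejected for artifacts")
        per_epoch = pd.DataFrame(rows)
        band_names = list(bands)
        totals = per_epoch[band_names].sum(axis=1)
        rel = per_epoch[band_names].div(totals, axis=0)
        per_epoch = per_epoch.join(rel.add_prefix("rel_"))
        summary = BandPowerSummary(
            per_epoch=per_epoch,
            relative={b: float(rel[b].mean()) for b in band_names},
            absolute={b: float(per_epoch[b].mean()) for b in band_names},
            n_epochs=len(per_epoch),
            epoch_duration_s=self.epoch_duration_s,
            bands=dict(bands))
        return summary


def relative_band_powers(rec: EEGRecording,
                         epochs: list[tuple[float, float]] | None = None,
                         bands: dict[str, tuple[float, float]] | None = None,
                         epoch_duration_s: float = 9.0) -> BandPowerSummary:
    """Convenience wrapper over :class:`BandPowerTransformer`."""
    return BandPowerTransformer(
        bands=bands, epoch_duration_s=epoch_duration_s,
    ).transform(rec, epochs=epochs)


# default band definitions, re-exported for callers that customize them
BANDS_DEFAULT = dict(BAND_EDGES)
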