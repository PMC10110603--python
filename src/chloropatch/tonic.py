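"""Tonic GABA_A current from the antagonist-induced baseline shift.

The tonic current is the difference of mean baseline current between an
epoch before and an epoch during antagonist application, computed only
over stretches devoid of synaptic events (at least 3 s accumulated per
epoch by default). Restricting to event-free segments matters: synaptic
charge would otherwise bias the means by the events' average current.

Sign convention: ``tonic_amplitude = I_post − I_pre``. At a −60 mV
holding potential a standing inward (negative) tonic current is blocked
by the antagonist, the baseline relaxes outward (toward 0 pA), and the
amplitude comes out positive with magnitude equal to the blocked current.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .events import MiniEvent
from .trace import Trace

__all__ = ["TonicResult", "TonicCurrentEstimator", "event_free_segments",
           "tonic_amplitude"]


@dataclass
class TonicResult:
    """Baseline means and their difference (see module sign convention)."""

    i_pre_pa: float
    i_post_pa: float
    tonic_amplitude_pa: float
    seconds_used_pre: float
    seconds_used_post: float
    segments_pre: list[tuple[float, float]]
    segments_post: list[tuple[float, float]]


def _event_times(events) -> np.ndarray:
    if events is None:
        return np.asarray([])
    times = [e.onset_s if isinstance(e, MiniEvent) else float(e)
             for e in events]
    return np.asarray(sorted(times))


def event_free_segments(trace: Trace, events, window: tuple[float, float],
                        required_total: float = 3.0,
                        pre_margin_s: float = 0.005,
                        post_margin_s: float = 0.050,
                        ) -> list[tuple[float, float]]:
    """Event-free intervals inside ``window`` totalling ``required_total`` s.

    Each event masks [onset − pre_margin, onset + post_margin]. Clean
    stretches are accumulated greedily from the start of the window
    inward (deterministic for a given event list), and the last one is
    trimmed so the total equals ``required_total`` exactly. Raises if
    the window cannot supply enough clean time, reporting how much is
    available.
    """
    t0, t1 = window
    if not (trace.t0 - 1e-9 <= t0 < t1 <= trace.t0 + trace.duration + 1e-9):
        raise ValueError("window outside trace")
    times = _event_times(events)
    # merge overlapping event masks, then walk their complement
    masks: list[list[float]] = []
    for t in times:
        a, b = t - pre_margin_s, t + post_margin_s
        if b <= t0 or a >= t1:
            continue
        a, b = max(a, t0), min(b, t1)
        if masks and a <= masks[-1][1]:
            masks[-1][1] = max(masks[-1][1], b)
        else:
            masks.append([a, b])
    clean: list[tuple[float, float]] = []
    cursor = t0
    for a, b in masks:
        if a > cursor:
            clean.append((cursor, a))
        cursor = max(cursor, b)
    if t1 > cursor:
        clean.append((cursor, t1))
    segments: list[tuple[float, float]] = []
    total = 0.0
    for a, b in clean:
        take = min(b - a, required_total - total)
        segments.append((a, a + take))
        total += take
        if total >= required_total - 1e-12:
            return segments
    available = sum(b - a for a, b in clean)
    raise ValueError(
        f"only {available:.3f} s of event-free time available in window "
        f"[{t0}, {t1}]; {required_total} s required")


class TonicCurrentEstimator(BaseEstimator):
    """Tonic-current amplitude from pre/post antagonist baselines.

    Parameters
    ----------
    antagonist_onset_s : float
        Time of antagonist application.
    settle_s : float
        Wash-in time excluded after onset before the post epoch starts.
    required_total_s : float
        Event-free seconds to accumulate in each epoch (≥ 3 by
        convention).
    pre_window_s, post_window_s : float
        Length of the search windows ending at onset / starting after
        settling.

    Attributes: ``i_pre_pa_``, ``i_post_pa_``, ``tonic_amplitude_pa_``,
    ``result_``.
    """

    def __init__(self, antagonist_onset_s: float, settle_s: float = 10.0,
                 required_total_s: float = 3.0,
                 pre_window_s: float | None = None,
                 post_window_s: float | None = None):
        self.antagonist_onset_s = antagonist_onset_s
        self.settle_s = settle_s
        self.required_total_s = required_total_s
        self.pre_window_s = pre_window_s
        self.post_window_s = post_window_s

    def fit(self, X: Trace, y=None, events=None):
        trace = X
        onset = self.antagonist_onset_s
        if not trace.t0 < onset < trace.t0 + trace.duration:
            raise ValueError("antagonist onset outside trace")
        pre_len = self.pre_window_s or (onset - trace.t0)
        post_start = onset + self.settle_s
        post_len = self.post_window_s or \
            (trace.t0 + trace.duration - post_start)
        if post_len <= 0:
            raise ValueError("no room for a post-antagonist window after "
                             "settling")
        pre_win = (onset - pre_len, onset)
        post_win = (post_start, post_start + post_len)
        seg_pre = event_free_segments(trace, events, pre_win,
                                      self.required_total_s)
        seg_post = event_free_segments(trace, events, post_win,
                                       self.required_total_s)
        self.i_pre_pa_ = _segments_mean(trace, seg_pre)
        self.i_post_pa_ = _segments_mean(trace, seg_post)
        self.tonic_amplitude_pa_ = self.i_post_pa_ - self.i_pre_pa_
        self.result_ = TonicResult(
            i_pre_pa=self.i_pre_pa_, i_post_pa=self.i_post_pa_,
            tonic_amplitude_pa=self.tonic_amplitude_pa_,
            seconds_used_pre=sum(b - a for a, b in seg_pre),
            seconds_used_post=sum(b - a for a, b in seg_post),
            segments_pre=seg_pre, segments_post=seg_post)
        return self


def _segments_mean(trace: Trace, segments) -> float:
    chunks = [trace.window(a, b) for a, b in segments]
    return float(np.mean(np.concatenate(chunks)))


def tonic_amplitude(trace: Trace, antagonist_onset: float,
                    settle: float = 10.0, events=None,
                    required_total: float = 3.0, **kwargs) -> TonicResult:
    """Convenience wrapper over :class:`TonicCurrentEstimator`."""
    est = TonicCurrentEstimator(
        antagonist_onset_s=antagonist_onset, settle_s=settle,
        required_total_s=required_total, **kwargs)
    est.fit(trace, events=events)
    return est.result_
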