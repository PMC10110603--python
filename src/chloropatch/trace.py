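"""Uniformly sampled time-series containers and their text I/O.

A :class:`Trace` is the substrate for every signal operation in the
package: voltage-clamp current records (pA) and EEG records (µV) alike.
Traces travel as two-column delimited text (time_s, value) with a JSON
sidecar carrying the sampling rate and units, so that every file is
self-describing and diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Trace", "EEGRecording", "read_trace", "write_trace",
           "read_annotations", "write_annotations"]


@dataclass
class Trace:
    """A uniformly sampled series with units.

    Parameters
    ----------
    samples : ndarray
        Sample values, one per time step.
    sampling_rate : float
        Samples per second (Hz); must be positive.
    units : str
        Physical units of the samples, e.g. ``"pA"`` or ``"uV"``.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    sampling_rate: float
    units: str = "pA"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Sample index of time ``t`` (clipped to the record)."""
        i = int(round((t - self.t0) * self.sampling_rate))
        return min(max(i, 0), self.n_samples - 1)

    def window(self, t_start: float, t_stop: float) -> np.ndarray:
        """Samples in the half-open interval [t_start, t_stop).

        Raises ``ValueError`` if the interval lies outside the record or
        is empty.
        """
        if t_stop <= t_start:
            raise ValueError("empty window: t_stop <= t_start")
        if t_start < self.t0 - 0.5 / self.sampling_rate or \
                t_stop > self.t0 + self.duration + 0.5 / self.sampling_rate:
            raise ValueError(
                f"window [{t_start}, {t_stop}) outside trace "
                f"[{self.t0}, {self.t0 + self.duration})")
        i0 = int(round((t_start - self.t0) * self.sampling_rate))
        i1 = int(round((t_stop - self.t0) * self.sampling_rate))
        i0 = max(i0, 0)
        i1 = min(i1, self.n_samples)
        if i1 <= i0:
            raise ValueError("window contains no samples")
        return self.samples[i0:i1]

    def slice(self, t_start: float, t_stop: float) -> "Trace":
        """A new Trace restricted to [t_start, t_stop)."""
        values = self.window(t_start, t_stop)
        i0 = max(int(round((t_start - self.t0) * self.sampling_rate)), 0)
        return Trace(values.copy(), self.sampling_rate, self.units,
                     t0=self.t0 + i0 / self.sampling_rate)


@dataclass
class EEGRecording:
    """An EEG channel with labelled annotation intervals.

    Annotations are a DataFrame with columns ``start_s``, ``end_s`` and
    ``label``; conventional labels are ``"nonrem"`` (spike-threshold
    baseline), ``"awake"`` (band-power epochs) and ``"artifact"``.
    """

    signal: Trace
    annotations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["start_s", "end_s", "label"]))

    def __post_init__(self) -> None:
        required = {"start_s", "end_s", "label"}
        if not required.issubset(self.annotations.columns):
            raise ValueError(f"annotations need columns {sorted(required)}")
        if len(self.annotations):
            bad = (self.annotations["start_s"] < self.signal.t0 - 1e-9) | \
                  (self.annotations["end_s"] >
                   self.signal.t0 + self.signal.duration + 1e-9)
            if bad.any():
                raise ValueError("annotation interval outside record")

    @property
    def sampling_rate(self) -> float:
        return self.signal.sampling_rate

    def intervals(self, label: str) -> list[tuple[float, float]]:
        sel = self.annotations[self.annotations["label"] == label]
        return list(zip(sel["start_s"], sel["end_s"]))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_trace(trace: Trace, path: str | Path) -> Path:
    """Write a trace as two-column delimited text plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.times, "value": trace.samples})
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    meta = {"sampling_rate_hz": trace.sampling_rate, "units": trace.units,
            "t0_s": trace.t0, "n_samples": trace.n_samples}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_trace(path: str | Path) -> Trace:
    """Read a trace written by :func:`write_trace`.

    The sidecar is authoritative for sampling rate and units; a missing
    or incomplete sidecar is a hard error (units are never guessed).
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("sampling_rate_hz", "units"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} missing field '{key}'")
    df = pd.read_csv(path, sep="\t")
    if "value" not in df.columns:
        raise ValueError(f"{path}: expected columns time_s, value")
    return Trace(df["value"].to_numpy(), meta["sampling_rate_hz"],
                 units=meta["units"], t0=float(meta.get("t0_s", 0.0)))


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    annotations[["start_s", "end_s", "label"]].to_csv(path, index=False)
    return path


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"start_s", "end_s", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    return df
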