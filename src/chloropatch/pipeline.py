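"""Orchestration: config loading, stage execution, report assembly.

A run is described by a YAML config (versioned schema) selecting stages
and their parameters; every tunable is echoed into the report together
with the seed and a hash of the canonical config, so re-running the same
config reproduces a numerically identical report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .clamp import (NernstParams, estimate_chloride, iv_points_from_traces)
from .eeg import (BandPowerTransformer, EpileptiformSpikeDetector,
                  discharge_rate)
from .events import detect_minis, summarize_minis
from .synth import (ClampGroundTruth, EEGGroundTruth, SynthConfig,
                    gen_eeg, gen_iv_protocol, gen_mini_trace,
                    gen_tonic_trace)
from .tonic import tonic_amplitude
from .trace import EEGRecording, Trace, read_annotations, read_trace

__all__ = ["RunConfig", "run_pipeline", "load_trace", "load_eeg",
           "load_config"]

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Validated run description.

    ``stages`` maps stage names (``simulate``, ``egaba``, ``minis``,
    ``tonic``, ``eeg``) to their parameter blocks.
    """

    seed: int = 0
    out_dir: Path | None = None
    stages: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    KNOWN_STAGES = ("simulate", "egaba", "minis", "tonic", "eeg")

    def validate(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version "
                             f"{self.schema_version}")
        # paths a configured simulate stage will create are exempt from
        # the exists-at-start rule
        generated: list[Path] = []
        if "simulate" in self.stages:
            out = (self.stages["simulate"] or {}).get("out", self.out_dir)
            if out is not None:
                generated.append(Path(out).resolve())
        for name, block in self.stages.items():
            if name not in self.KNOWN_STAGES:
                raise ValueError(f"unknown stage '{name}'")
            for key in ("trace", "traces", "annotations", "recording"):
                path = (block or {}).get(key)
                if path is None or Path(path).exists():
                    continue
                resolved = Path(path).resolve()
                if any(root == resolved or root in resolved.parents
                       for root in generated):
                    continue
                raise FileNotFoundError(
                    f"stage '{name}': input path does not exist: {path}")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=Path(raw["out_dir"]) if raw.get("out_dir") else None,
        stages=raw.get("stages", {}),
        schema_version=int(raw.get("schema_version", SCHEMA_VERSION)))
    cfg.validate()
    return cfg


def load_trace(path: str | Path) -> Trace:
    """Read a delimited trace with its sidecar metadata (units required)."""
    return read_trace(path)


def load_eeg(path: str | Path, annotations: str | Path | None = None,
             channel: str | int = 0) -> EEGRecording:
    """Load an EEG record from delimited text or EDF.

    EDF files are read through :mod:`mne` (channel selected by label or
    index); delimited files use the package's sidecar dialect.
    Annotations, if given, are a CSV of (start_s, end_s, label).
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                "reading EDF requires the optional 'mne' dependency") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        picks = [channel] if isinstance(channel, str) else [
            raw.ch_names[int(channel)]]
        data = raw.get_data(picks=picks)[0] * 1e6  # volts → µV
        trace = Trace(data, raw.info["sfreq"], units="uV")
    else:
        trace = read_trace(path)
    ann = read_annotations(annotations) if annotations is not None else None
    if ann is not None:
        return EEGRecording(trace, ann)
    return EEGRecording(trace)


def _config_hash(cfg: RunConfig) -> str:
    canon = yaml.safe_dump({
        "seed": cfg.seed, "schema_version": cfg.schema_version,
        "stages": cfg.stages}, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and return the report dict.

    The report carries provenance (config hash, seed, version) and, per
    stage, either its results or — if the stage raised — the diagnostic,
    leaving earlier stages' results intact.
    """
    cfg.validate()
    report: dict = {
        "provenance": {"config_hash": _config_hash(cfg), "seed": cfg.seed,
                       "version": __version__,
                       "schema_version": cfg.schema_version},
        "config": {"seed": cfg.seed, "stages": cfg.stages},
        "stages": {}, "warnings": [],
    }
    for name in cfg.KNOWN_STAGES:
        if name not in cfg.stages:
            continue
        block = cfg.stages[name] or {}
        try:
            report["stages"][name] = _STAGE_RUNNERS[name](cfg, block)
        except Exception as exc:  # noqa: BLE001 — reported, not swallowed
            report["stages"][name] = {"error": f"{type(exc).__name__}: {exc}"}
    if cfg.out_dir is not None:
        cfg.out_dir.mkdir(parents=True, exist_ok=True)
        (cfg.out_dir / "report.json").write_text(
            json.dumps(report, indent=1, default=_jsonable))
    return report


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return str(obj)


def _run_simulate(cfg: RunConfig, block: dict) -> dict:
    from .trace import write_trace
    kind = block.get("kind", "minis")
    out = Path(block.get("out", cfg.out_dir or "."))
    out.mkdir(parents=True, exist_ok=True)
    scfg = SynthConfig(seed=cfg.seed,
                       sampling_rate=block.get("sampling_rate", 10_000.0),
                       duration=block.get("duration", 30.0),
                       noise_sd=block.get("noise_sd", 2.0))
    written = []
    truth: dict = {}
    if kind == "iv":
        gt = ClampGroundTruth(
            true_e_rev=block.get("true_e_rev", -70.0),
            true_rs=block.get("rs", 10.0))
        traces, _ = gen_iv_protocol(scfg, gt)
        for v, tr in traces.items():
            p = out / f"iv_{int(v)}mV.tsv"
            write_trace(tr, p)
            written.append(str(p))
        truth = {"true_e_rev": gt.true_e_rev, "rs": gt.true_rs,
                 "command_schedule": list(gt.command_schedule)}
    elif kind == "minis":
        trace, times = gen_mini_trace(scfg, rate=block.get("rate", 5.0),
                                      amp_mean=block.get("amp_mean", 20.0))
        p = out / "minis.tsv"
        write_trace(trace, p)
        written.append(str(p))
        truth = {"event_times": times.tolist()}
    elif kind == "tonic":
        trace, t = gen_tonic_trace(
            scfg, tonic_shift=block.get("tonic_shift", 10.0),
            antagonist_onset=block.get("antagonist_onset",
                                       scfg.duration / 2),
            mini_rate=block.get("mini_rate", 3.0))
        p = out / "tonic.tsv"
        write_trace(trace, p)
        written.append(str(p))
        truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in t.items()}
    elif kind == "eeg":
        gt = EEGGroundTruth(
            spike_times=tuple(block.get("spike_times", ())),
            band_mix=tuple(block.get("band_mix", (0.25,) * 4)))
        rec, _ = gen_eeg(scfg, gt)
        p = out / "eeg.tsv"
        write_trace(rec.signal, p)
        written.append(str(p))
        truth = {"spike_times": list(gt.spike_times),
                 "band_mix": list(gt.band_mix)}
    else:
        raise ValueError(f"unknown simulate kind '{kind}'")
    (out / f"{kind}_truth.json").write_text(
        json.dumps(truth, indent=1, default=_jsonable))
    return {"kind": kind, "files": written, "truth": truth}


def _run_egaba(cfg: RunConfig, block: dict) -> dict:
    traces_dir = Path(block["traces"])
    stim_time = block.get("stim_time", 0.2)
    rs = float(block.get("rs", 0.0))
    traces = {}
    for p in sorted(traces_dir.glob("iv_*mV.tsv")):
        v = float(p.stem.split("_")[1].removesuffix("mV"))
        traces[v] = read_trace(p)
    if not traces:
        raise FileNotFoundError(f"no iv_*mV.tsv traces in {traces_dir}")
    points = iv_points_from_traces(traces, stim_time=stim_time, r_s_mohm=rs)
    params = NernstParams(cl_out_mm=block.get("cl_out_mm", 132.5),
                          temperature_k=block.get("temperature_k", 303.15))
    est = estimate_chloride(points, params)
    return {"e_gaba_mv": est.e_gaba_mv, "cl_in_mm": est.cl_in_mm,
            "cl_out_mm": params.cl_out_mm,
            "temperature_k": params.temperature_k,
            "rs_mohm": rs,
            "fit": {"slope_ns": est.fit.slope_ns,
                    "residual_rms_pa": est.fit.residual_rms_pa,
                    "extrapolated": est.fit.extrapolated,
                    "n_points": est.fit.n_points}}


def _run_minis(cfg: RunConfig, block: dict) -> dict:
    trace = read_trace(block["trace"])
    events = detect_minis(trace, polarity=block.get("polarity", "inward"),
                          threshold_multiplier=block.get("thresh", 3.5))
    summary = summarize_minis(events, trace.duration,
                              frequency_unit=block.get("frequency_unit",
                                                       "per_s"))
    return {"n_events": summary.n_events, "frequency": summary.frequency,
            "frequency_unit": summary.frequency_unit,
            "mean_amplitude_pa": summary.mean_amplitude_pa,
            "mean_rise_ms": summary.mean_rise_ms,
            "mean_decay_ms": summary.mean_decay_ms}


def _run_tonic(cfg: RunConfig, block: dict) -> dict:
    trace = read_trace(block["trace"])
    onset = float(block["onset"])
    settle = float(block.get("settle", 10.0))
    pre = trace.slice(trace.t0, onset)
    events = detect_minis(pre, polarity=block.get("polarity", "inward"),
                          threshold_multiplier=block.get("thresh", 3.5)) \
        if block.get("detect_events", True) else None
    res = tonic_amplitude(trace, onset, settle=settle, events=events,
                          required_total=block.get("required_total", 3.0))
    return {"i_pre_pa": res.i_pre_pa, "i_post_pa": res.i_post_pa,
            "tonic_amplitude_pa": res.tonic_amplitude_pa,
            "seconds_used_pre": res.seconds_used_pre,
            "seconds_used_post": res.seconds_used_post}


def _run_eeg(cfg: RunConfig, block: dict) -> dict:
    rec = load_eeg(block["recording"], annotations=block.get("annotations"))
    out: dict = {}
    if "baseline" in block or rec.intervals("nonrem"):
        det = EpileptiformSpikeDetector(
            threshold_multiplier=block.get("k", 4.0))
        det.fit(rec, baseline_interval=tuple(block["baseline"])
                if "baseline" in block else None)
        rate = discharge_rate(det.discharges_, rec.signal.duration)
        out["spikes"] = {"n_spikes": det.n_spikes_,
                         "threshold_uv": det.threshold_uv_,
                         "n_discharges": rate["count"],
                         "discharge_rate_per_hour": rate["rate_per_hour"]}
    if "epochs" in block:
        summary = BandPowerTransformer(
            epoch_duration_s=block.get("epoch_duration", 9.0)).transform(
            rec, epochs=[tuple(e) for e in block["epochs"]])
        out["band_power"] = {"relative": summary.relative,
                             "n_epochs": summary.n_epochs}
    if not out:
        raise ValueError("eeg stage needs a baseline (spikes) and/or "
                         "epochs (band power)")
    return out


_STAGE_RUNNERS = {
    "simulate": _run_simulate,
    "egaba": _run_egaba,
    "minis": _run_minis,
    "tonic": _run_tonic,
    "eeg": _run_eeg,
}
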