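"""Trace/summary file formats and the run-configuration schema.

Traces are single-file portable CSVs: comment lines prefixed ``#`` carry the
channel and protocol metadata, followed by a ``time_s,output_uV`` header and
the samples (time with 4 decimal places, output with 6 significant digits).
Run configurations are YAML files with the flat block structure
``sources / films / bridge / protocol / noise / analysis / replicates``;
unknown keys are rejected so that typos cannot silently change a run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .analyze import AnalysisWindow, MeasurementSummary
from .simulate import (
    BridgeConfig,
    InjectionProgram,
    OdorSource,
    ReceptorFilm,
    SensorTrace,
    SorptionParams,
    Undulation,
)

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "read_trace",
    "write_trace",
    "write_summary",
    "read_summary",
    "format_mean_std",
    "write_provenance",
]


class ConfigError(ValueError):
    """A run configuration failed schema validation."""


# ---------------------------------------------------------------------------
# trace files
# ---------------------------------------------------------------------------

def write_trace(trace: SensorTrace, path: str | Path) -> None:
    """Write one channel's trace as commented CSV."""
    path = Path(path)
    lines = ["# rdcsense trace v1", f"# channel: {trace.channel}"]
    p = trace.program
    if p is not None:
        lines += [
            f"# mode: {p.mode}",
            f"# sampling_rate_hz: {p.sampling_rate_hz:g}",
            f"# total_duration_s: {p.total_duration_s:g}",
            f"# flow_rate_ml_min: {p.flow_rate_ml_min:g}",
            "# segments: " + ";".join(f"{s}:{d:g}" for s, d in p.segments),
        ]
    body = "\n".join(
        f"{t:.4f},{v:.6g}" for t, v in zip(trace.time, trace.output)
    )
    path.write_text("\n".join(lines) + "\ntime_s,output_uV\n" + body + "\n")


def read_trace(path: str | Path) -> SensorTrace:
    """Read a trace CSV, validating the sampling grid.

    Grid irregularities (non-monotone or duplicated timestamps, non-finite
    outputs) are rejected with the offending line number.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    times: list[float] = []
    outputs: list[float] = []
    header_seen = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                text = line.lstrip("#").strip()
                if ":" in text:
                    key, _, value = text.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                if line.replace(" ", "") != "time_s,output_uV":
                    raise ValueError(
                        f"{path}:{lineno}: missing 'time_s,output_uV' header"
                    )
                header_seen = True
                continue
            try:
                t_str, v_str = line.split(",")
                t, v = float(t_str), float(v_str)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed sample line") from exc
            if not np.isfinite(v):
                raise ValueError(f"{path}:{lineno}: non-finite output value")
            if times and t <= times[-1]:
                raise ValueError(
                    f"{path}:{lineno}: non-increasing or duplicated timestamp {t_str}"
                )
            times.append(t)
            outputs.append(v)
    if not header_seen:
        raise ValueError(f"{path}: missing 'time_s,output_uV' header")
    if len(times) < 2:
        raise ValueError(f"{path}: trace needs at least two samples")
    program = None
    if "segments" in meta:
        segments = tuple(
            (name, float(dur))
            for name, _, dur in (s.partition(":") for s in meta["segments"].split(";"))
        )
        program = InjectionProgram(
            segments=segments,
            sampling_rate_hz=float(meta["sampling_rate_hz"]),
            total_duration_s=float(meta["total_duration_s"]),
            mode=meta.get("mode", "normal"),
            flow_rate_ml_min=float(meta.get("flow_rate_ml_min", 30.0)),
        )
    return SensorTrace(
        np.asarray(times), np.asarray(outputs),
        channel=meta.get("channel", ""), program=program,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

_SUMMARY_COLUMNS = (
    "channel",
    "measurement_type",
    "intensity_uV",
    "noise_raw_uV",
    "noise_avg_uV",
    "noise_theory_uV",
    "snr",
)


def write_summary(summaries: list[MeasurementSummary], path: str | Path) -> None:
    """Write per-measurement summaries as CSV with stable column order."""
    if not summaries:
        raise ValueError("no summaries to write")
    rows = [
        {
            "channel": s.channel,
            "measurement_type": s.measurement_type,
            "intensity_uV": s.signal_intensity_uv,
            "noise_raw_uV": s.noise_raw_uv,
            "noise_avg_uV": s.noise_avg_uv,
            "noise_theory_uV": s.noise_theory_uv,
            "snr": s.snr,
        }
        for s in summaries
    ]
    df = pd.DataFrame(rows, columns=list(_SUMMARY_COLUMNS))
    df.to_csv(path, index=False, float_format="%.4g")


def read_summary(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: summary is missing columns {sorted(missing)}")
    return df


def format_mean_std(mean: float, std: float) -> str:
    """Render ``mean ± std`` with 4 significant digits, e.g. ``5.000 ± 1.414``."""

    def fmt(v: float) -> str:
        return f"{v:#.4g}".rstrip(".")

    return f"{fmt(mean)} ± {fmt(std)}"


def write_provenance(
    out_dir: str | Path, seed: int | None, config_path: str | Path | None
) -> None:
    """Drop a machine-readable provenance record into an output directory."""
    from . import __version__

    record: dict[str, Any] = {"package": "rdcsense", "version": __version__, "seed": seed}
    if config_path is not None:
        digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
        record["config"] = str(config_path)
        record["config_sha256"] = digest
    Path(out_dir, "provenance.json").write_text(json.dumps(record, indent=2) + "\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolSpec:
    mode: str
    samples: tuple[str, ...]
    interval_s: float = 5.0
    total_duration_s: float = 120.0
    sampling_rate_hz: float = 100.0
    flow_rate_ml_min: float = 30.0


@dataclass(frozen=True)
class NoiseSpec:
    gaussian_sigma_uv: float = 0.0
    drift_slope_uv_per_s: float = 0.0
    undulation: Undulation | None = None


@dataclass(frozen=True)
class AnalysisSpec:
    window: AnalysisWindow = AnalysisWindow()
    cycle_duration_s: float = 10.0
    n_repetitions: int = 6
    fit_window_s: tuple[float, float] = (9.0, 10.0)


@dataclass(frozen=True)
class RunConfig:
    """Validated union of every module's parameter block."""

    sources: dict[str, OdorSource]
    films: dict[str, ReceptorFilm]
    bridge: BridgeConfig
    protocol: ProtocolSpec
    noise: NoiseSpec
    analysis: AnalysisSpec
    replicates: int = 6


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def _as_mapping(obj: Any, where: str) -> dict:
    if not isinstance(obj, dict):
        raise ConfigError(f"{where} must be a mapping")
    return obj


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    raw = _as_mapping(raw, "top level")
    _check_keys(
        raw,
        {"sources", "films", "bridge", "protocol", "noise", "analysis", "replicates"},
        "top level",
    )
    try:
        sources = {
            name: OdorSource(name, _as_mapping(conc, f"sources.{name}"))
            for name, conc in _as_mapping(raw.get("sources", {}), "sources").items()
        }

        films = {}
        for name, comps in _as_mapping(raw.get("films", {}), "films").items():
            params = {}
            for comp, p in _as_mapping(comps, f"films.{name}").items():
                p = _as_mapping(p, f"films.{name}.{comp}")
                _check_keys(
                    p, {"partition", "tau_s", "responsivity"}, f"films.{name}.{comp}"
                )
                params[comp] = SorptionParams(
                    partition=float(p.get("partition", 0.0)),
                    tau_s=float(p["tau_s"]),
                    responsivity=float(p.get("responsivity", 0.0)),
                )
            films[name] = ReceptorFilm(name, params)

        b = _as_mapping(raw.get("bridge", {}), "bridge")
        _check_keys(b, {"voltage_v", "arm_weights"}, "bridge")
        bridge = BridgeConfig(
            bridge_voltage_v=float(b.get("voltage_v", -1.0)),
            arm_weights=tuple(b.get("arm_weights", (1.0, -1.0, 1.0, -1.0))),
        )

        p = _as_mapping(raw.get("protocol", {}), "protocol")
        _check_keys(
            p,
            {
                "mode",
                "samples",
                "interval_s",
                "total_duration_s",
                "sampling_rate_hz",
                "flow_rate_ml_min",
            },
            "protocol",
        )
        if "mode" not in p or "samples" not in p:
            raise ConfigError("protocol block needs 'mode' and 'samples'")
        protocol = ProtocolSpec(
            mode=str(p["mode"]),
            samples=tuple(p["samples"]),
            interval_s=float(p.get("interval_s", 5.0)),
            total_duration_s=float(p.get("total_duration_s", 120.0)),
            sampling_rate_hz=float(p.get("sampling_rate_hz", 100.0)),
            flow_rate_ml_min=float(p.get("flow_rate_ml_min", 30.0)),
        )
        for s in protocol.samples:
            if s not in sources:
                raise ConfigError(f"protocol references unknown source {s!r}")

        n = _as_mapping(raw.get("noise", {}), "noise")
        _check_keys(
            n, {"gaussian_sigma_uv", "drift_slope_uv_per_s", "undulation"}, "noise"
        )
        und = None
        if n.get("undulation") is not None:
            u = _as_mapping(n["undulation"], "noise.undulation")
            _check_keys(u, {"amplitude_uv", "frequency_hz", "phase_rad"}, "noise.undulation")
            und = Undulation(
                amplitude_uv=float(u["amplitude_uv"]),
                frequency_hz=float(u["frequency_hz"]),
                phase_rad=float(u.get("phase_rad", 0.0)),
            )
        noise = NoiseSpec(
            gaussian_sigma_uv=float(n.get("gaussian_sigma_uv", 0.0)),
            drift_slope_uv_per_s=float(n.get("drift_slope_uv_per_s", 0.0)),
            undulation=und,
        )

        a = _as_mapping(raw.get("analysis", {}), "analysis")
        _check_keys(
            a,
            {
                "window_start_s",
                "window_end_s",
                "cycle_duration_s",
                "n_repetitions",
                "fit_window_s",
            },
            "analysis",
        )
        analysis = AnalysisSpec(
            window=AnalysisWindow(
                t_start_s=float(a.get("window_start_s", 55.0)),
                t_end_s=float(a.get("window_end_s", 115.0)),
            ),
            cycle_duration_s=float(a.get("cycle_duration_s", 10.0)),
            n_repetitions=int(a.get("n_repetitions", 6)),
            fit_window_s=tuple(float(x) for x in a.get("fit_window_s", (9.0, 10.0))),
        )

        replicates = int(raw.get("replicates", 6))
    except ConfigError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc

    return RunConfig(
        sources=sources,
        films=films,
        bridge=bridge,
        protocol=protocol,
        noise=noise,
        analysis=analysis,
        replicates=replicates,
    )
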