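"""Signal-processing pipeline for repetitive odor-injection measurements.

The pipeline turns a raw sensor trace into a per-measurement summary:

1. extract the steady-state analysis window (default 55–115 s);
2. segment it into N injection cycles (default N = 6, 10 s each), each cycle
   spanning [Sample-1 start, next Sample-1 start);
3. baseline-correct each cycle so its output is 0 at the Sample-1 start;
4. average the cycles pointwise;
5. estimate noise as the RMS of residuals about a straight-line fit over the
   final second of a cycle (default 9.0–10.0 s);
6. report signal intensity (output at 5 s minus output at 0 s), the
   theoretical averaged noise (raw noise / sqrt(N)), and S/N.

No low-pass or moving-average filtering is applied anywhere: smoothing would
attenuate the rapid sensor response that carries the sorption kinetics.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Sequence
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .simulate import SensorTrace

__all__ = [
    "AnalysisWindow",
    "CycleSet",
    "MeasurementSummary",
    "CycleConvergence",
    "extract_window",
    "segment_cycles",
    "baseline_correct",
    "average_cycles",
    "noise_level",
    "signal_intensity",
    "theoretical_noise",
    "propagate_difference_noise",
    "difference_trace",
    "analyze_trace",
    "snr_summary",
    "cycle_convergence",
]


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open time window [t_start, t_end) used for averaging."""

    t_start_s: float = 55.0
    t_end_s: float = 115.0

    def __post_init__(self) -> None:
        if self.t_end_s <= self.t_start_s:
            raise ValueError("window end must be after window start")


@dataclass(frozen=True)
class CycleSet:
    """N repetition cycles of M samples each, as an (N, M) matrix of μV."""

    cycles: np.ndarray
    cycle_duration_s: float
    sampling_rate_hz: float
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        c = np.asarray(self.cycles, dtype=float)
        if c.ndim != 2:
            raise ValueError("cycles must be a 2-D (N, M) array")
        object.__setattr__(self, "cycles", c)

    @property
    def n_repetitions(self) -> int:
        return self.cycles.shape[0]

    @property
    def cycle_time(self) -> np.ndarray:
        """Local time axis of one cycle, starting at 0 s."""
        return np.arange(self.cycles.shape[1]) / self.sampling_rate_hz


@dataclass(frozen=True)
class MeasurementSummary:
    """Derived statistics of one measurement (one channel, one protocol)."""

    channel: str
    measurement_type: str  # 'rdc' | 'normal' | 'difference'
    signal_intensity_uv: float  # signed
    noise_raw_uv: float
    noise_avg_uv: float
    noise_theory_uv: float
    snr: float

    def __post_init__(self) -> None:
        for name in ("noise_raw_uv", "noise_avg_uv", "noise_theory_uv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def extract_window(
    trace: SensorTrace,
    window: AnalysisWindow | None = None,
    cycle_duration_s: float | None = None,
) -> SensorTrace:
    """Return the samples with t in [t_start, t_end), re-timed to start at 0.

    Both boundaries must lie on the sampling grid.  If ``cycle_duration_s``
    is given, the window length must be an integer multiple of it.
    """
    if window is None:
        window = AnalysisWindow()
    fs = trace.sampling_rate_hz
    if cycle_duration_s is not None:
        ratio = (window.t_end_s - window.t_start_s) / cycle_duration_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"window length {window.t_end_s - window.t_start_s} s is not an "
                f"integer multiple of the cycle duration {cycle_duration_s} s"
            )
    k0 = (window.t_start_s - trace.time[0]) * fs
    k1 = (window.t_end_s - trace.time[0]) * fs
    for name, k in (("start", k0), ("end", k1)):
        if abs(k - round(k)) > 1e-6:
            raise ValueError(f"window {name} is not on the sampling grid")
    i0, i1 = round(k0), round(k1)
    if i0 < 0 or i1 > len(trace):
        raise ValueError("analysis window extends outside the trace")
    out = trace.output[i0:i1]
    time = np.arange(i1 - i0) / fs
    return SensorTrace(time, out, channel=trace.channel, program=trace.program)


def segment_cycles(
    windowed: SensorTrace,
    cycle_duration_s: float = 10.0,
    expected_n: int | None = None,
) -> CycleSet:
    """Split a windowed trace into equal repetition cycles.

    The caller must have aligned the window start with a Sample-1 injection
    start; with the standard schedule (Sample 2 first at t = 0, 5 s
    intervals) the default 55 s window start is such an alignment.
    """
    fs = windowed.sampling_rate_hz
    m_float = cycle_duration_s * fs
    m = round(m_float)
    if abs(m_float - m) > 1e-6 or m < 1:
        raise ValueError("cycle duration must be an integer multiple of the sampling period")
    n_samples = len(windowed)
    if n_samples % m != 0:
        raise ValueError(
            f"window of {n_samples} samples does not divide into cycles of {m} samples"
        )
    n = n_samples // m
    if expected_n is not None and n != expected_n:
        raise ValueError(f"expected {expected_n} cycles, found {n}")
    return CycleSet(
        cycles=windowed.output.reshape(n, m).copy(),
        cycle_duration_s=float(cycle_duration_s),
        sampling_rate_hz=fs,
    )


def baseline_correct(cycle_set: CycleSet) -> CycleSet:
    """Zero each cycle at its Sample-1 injection start (first sample)."""
    corrected = cycle_set.cycles - cycle_set.cycles[:, :1]
    return replace(cycle_set, cycles=corrected, baseline_corrected=True)


def average_cycles(cycle_set: CycleSet) -> np.ndarray:
    """Pointwise mean over the N repetition cycles."""
    return cycle_set.cycles.mean(axis=0)


def noise_level(
    cycle: np.ndarray,
    sampling_rate_hz: float,
    fit_window_s: tuple[float, float] = (9.0, 10.0),
    residual_dof: int = 0,
) -> float:
    """RMS of residuals about a straight-line fit over the fit window.

    The output is approximately linear over the last second of a cycle, so
    the residuals about an ordinary least-squares line estimate the noise.
    The default divisor is the sample count n (population RMS of the
    residuals); ``residual_dof=2`` selects the unbiased OLS divisor n - 2.
    """
    cycle = np.asarray(cycle, dtype=float)
    lo, hi = fit_window_s
    i0, i1 = round(lo * sampling_rate_hz), round(hi * sampling_rate_hz)
    if i0 < 0 or i1 > cycle.size or i1 - i0 < 3:
        raise ValueError("fit window must lie inside the cycle and contain >= 3 samples")
    t = np.arange(i0, i1) / sampling_rate_hz
    y = cycle[i0:i1]
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    n = resid.size
    return float(np.sqrt(np.sum(resid**2) / (n - residual_dof)))


def signal_intensity(
    averaged_cycle: np.ndarray,
    sampling_rate_hz: float,
    peak_time_s: float = 5.0,
) -> float:
    """Output at the injection peak minus output at the cycle start (signed).

    For a baseline-corrected cycle the start sample is 0, so this is simply
    the output at 5 s.  The single grid sample is used — no local smoothing.
    """
    averaged_cycle = np.asarray(averaged_cycle, dtype=float)
    k = peak_time_s * sampling_rate_hz
    if abs(k - round(k)) > 1e-6:
        raise ValueError(f"peak time {peak_time_s} s is not on the sampling grid")
    k = round(k)
    if not (0 <= k < averaged_cycle.size):
        raise ValueError("peak time lies outside the cycle")
    return float(averaged_cycle[k] - averaged_cycle[0])


def theoretical_noise(noise_raw_uv: float, n_repetitions: int) -> float:
    """Expected noise after averaging N repetitions: raw / sqrt(N).

    Valid for i.i.d. Gaussian noise, for which the noise level is inversely
    proportional to the square root of the number of averaged repetitions.
    """
    if noise_raw_uv < 0:
        raise ValueError("raw noise must be >= 0")
    if n_repetitions < 1:
        raise ValueError("number of repetitions must be >= 1")
    return noise_raw_uv / math.sqrt(n_repetitions)


def propagate_difference_noise(sigma_a_uv: float, sigma_b_uv: float) -> float:
    """Noise of a difference of two independent traces: sqrt(sa^2 + sb^2)."""
    if sigma_a_uv < 0 or sigma_b_uv < 0:
        raise ValueError("noise levels must be >= 0")
    return math.hypot(sigma_a_uv, sigma_b_uv)


def difference_trace(trace_a: SensorTrace, trace_b: SensorTrace) -> SensorTrace:
    """Pointwise trace_a - trace_b on identical sampling grids.

    To reproduce the conventional sign for a differenced pair of normal
    measurements, pass the second sample's trace as ``trace_a`` and the first
    sample's as ``trace_b``.
    """
    if len(trace_a) != len(trace_b) or not np.allclose(
        trace_a.time, trace_b.time, rtol=0.0, atol=1e-9
    ):
        raise ValueError("traces are on different sampling grids")
    return SensorTrace(
        trace_a.time.copy(),
        trace_a.output - trace_b.output,
        channel=trace_a.channel,
        program=trace_a.program,
    )


def analyze_trace(
    trace: SensorTrace,
    window: AnalysisWindow | None = None,
    cycle_duration_s: float = 10.0,
    n_repetitions: int | None = None,
    fit_window_s: tuple[float, float] = (9.0, 10.0),
    peak_time_s: float = 5.0,
    measurement_type: str | None = None,
    residual_dof: int = 0,
) -> MeasurementSummary:
    """Run the full pipeline on one trace and summarise it.

    ``noise_raw_uv`` is the mean of the per-cycle noise levels before
    averaging; ``noise_avg_uv`` is the noise level of the averaged cycle;
    ``noise_theory_uv`` is raw / sqrt(N).  S/N is |intensity| / noise_avg;
    a zero noise floor is reported as 0 with S/N = NaN and a warning.
    """
    w = extract_window(trace, window, cycle_duration_s=cycle_duration_s)
    cs = segment_cycles(w, cycle_duration_s, expected_n=n_repetitions)
    noise_raw = float(
        np.mean(
            [
                noise_level(row, cs.sampling_rate_hz, fit_window_s, residual_dof)
                for row in cs.cycles
            ]
        )
    )
    corrected = baseline_correct(cs)
    avg = average_cycles(corrected)
    noise_avg = noise_level(avg, cs.sampling_rate_hz, fit_window_s, residual_dof)
    intensity = signal_intensity(avg, cs.sampling_rate_hz, peak_time_s)
    if noise_avg > 0:
        snr = abs(intensity) / noise_avg
    else:
        warnings.warn("zero noise floor; S/N reported as NaN", stacklevel=2)
        snr = float("nan")
    if measurement_type is None:
        measurement_type = trace.program.mode if trace.program is not None else "unknown"
    return MeasurementSummary(
        channel=trace.channel,
        measurement_type=measurement_type,
        signal_intensity_uv=intensity,
        noise_raw_uv=noise_raw,
        noise_avg_uv=noise_avg,
        noise_theory_uv=theoretical_noise(noise_raw, cs.n_repetitions),
        snr=snr,
    )


_SUMMARY_FIELDS = (
    "signal_intensity_uv",
    "noise_raw_uv",
    "noise_avg_uv",
    "noise_theory_uv",
    "snr",
)


def snr_summary(summaries: Sequence[MeasurementSummary]) -> pd.DataFrame:
    """Mean and sample standard deviation of each statistic over replicates.

    S/N is computed per measurement *before* aggregation (the mean of the
    per-replicate ratios, which in general differs from the ratio of the
    means).  Requires at least two replicates.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two replicate measurements")
    data = {f: np.array([getattr(s, f) for s in summaries]) for f in _SUMMARY_FIELDS}
    return pd.DataFrame(
        {
            "mean": {f: v.mean() for f, v in data.items()},
            "std": {f: v.std(ddof=1) for f, v in data.items()},
        }
    )


@dataclass(frozen=True)
class CycleConvergence:
    """Consecutive-cycle change diagnostics for steady-state detection.

    ``deltas[k]`` is ``max |cycle_{k+1} - cycle_k|``; ``converged_at`` is the
    first k >= 1 with ``deltas[k] <= rel_tol * deltas[0]`` (None if the trace
    never settles within the recorded cycles).
    """

    deltas: np.ndarray
    converged_at: int | None
    rel_tol: float


def cycle_convergence(
    trace: SensorTrace,
    cycle_duration_s: float = 10.0,
    rel_tol: float = 0.05,
) -> CycleConvergence:
    """Check that the trace has become cycle-periodic (steady state).

    With first-order sorption kinetics the consecutive-cycle change decays
    geometrically with ratio exp(-cycle_duration / tau_max), so the default
    5% relative tolerance corresponds to roughly three time constants of the
    slowest component.  The check is diagnostic only; it warns on
    non-convergence and never alters the analysis.
    """
    fs = trace.sampling_rate_hz
    m = round(cycle_duration_s * fs)
    n_cycles = len(trace) // m
    if n_cycles < 2:
        raise ValueError("need at least two full cycles to assess convergence")
    mat = trace.output[: n_cycles * m].reshape(n_cycles, m)
    deltas = np.abs(np.diff(mat, axis=0)).max(axis=1)
    converged_at: int | None = None
    if deltas[0] == 0.0:
        converged_at = 1
    else:
        hits = np.nonzero(deltas <= rel_tol * deltas[0])[0]
        hits = hits[hits >= 1]
        if hits.size:
            converged_at = int(hits[0])
    if converged_at is None:
        warnings.warn(
            "sensing output has not reached a cycle-periodic steady state",
            stacklevel=2,
        )
    return CycleConvergence(deltas=deltas, converged_at=converged_at, rel_tol=rel_tol)
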