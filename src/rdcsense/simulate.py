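"""Forward model of membrane-type surface stress sensor (MSS) odor measurements.

An MSS is a MEMS nanomechanical gas sensor: a polymer receptor film coated on
a suspended membrane absorbs gas molecules, the film expands, and the induced
surface stress is read out by four piezoresistors wired as a Wheatstone
bridge.  This module simulates such a sensor exposed to a programmed sequence
of odor injections:

* sorption of each gas component into the film follows first-order kinetics
  with a per-component partition coefficient ``K``, time constant ``tau`` and
  responsivity ``g`` (fractional resistance change per unit sorbed quantity);
* the film strain ``s(t) = sum_i g_i * q_i(t)`` is transduced through the
  bridge, ``Vout = (VB/4) * (dR1/R1 - dR2/R2 + dR3/R3 - dR4/R4)``, with the
  default full-bridge arm pattern (+1, -1, +1, -1) giving ``Vout = VB * s``;
* measurement imperfections are added as i.i.d. Gaussian noise, a linear
  baseline drift, and an optional sinusoidal undulation.

Two injection protocols are supported.  A *normal* measurement alternates one
sample odor with cleaned carrier air; the schedule starts with the carrier
(the sample occupies the Sample-1 vial, the Sample-2 vial is empty, and the
first injection draws from Sample 2).  An *rDC* (repetitive direct
comparison) measurement alternates two sample odors with no carrier purge in
between, starting with Sample 2, so that components common to both samples
cancel and only the odor difference drives the alternating signal.

All kinetics are integrated segment-wise with the exact exponential update of
the first-order ODE on the sampling grid, so there is no integrator
tolerance to configure.  Samples lie at ``t = k / f`` for
``k = 0 .. total_duration * f`` inclusive; valve segments are half-open
``[start, end)`` and the sample at a valve switch belongs to the new segment.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np

#: Reserved source id for deodorized, dehumidified carrier air (zero
#: concentration of every component).
CARRIER_ID = "carrier"

__all__ = [
    "CARRIER_ID",
    "OdorSource",
    "SorptionParams",
    "ReceptorFilm",
    "InjectionProgram",
    "NoiseModel",
    "Undulation",
    "BridgeConfig",
    "SensorTrace",
    "build_protocol",
    "time_grid",
    "sorbed_response",
    "film_strain",
    "transduce_bridge",
    "add_noise_and_drift",
    "simulate_measurement",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OdorSource:
    """A named gas source: map from component id to concentration.

    Concentrations are in arbitrary concentration units (the model is linear,
    so only ratios matter).  Odors with a "common base + distinct flavor"
    structure are expressed by sharing high-concentration component ids
    between two sources and giving each a low-concentration distinct one.
    """

    name: str
    concentrations: Mapping[str, float]

    def __post_init__(self) -> None:
        conc = dict(self.concentrations)
        for comp, c in conc.items():
            if not (isinstance(c, (int, float)) and math.isfinite(c)):
                raise ValueError(f"source {self.name!r}: concentration of {comp!r} is not finite")
            if c < 0:
                raise ValueError(f"source {self.name!r}: concentration of {comp!r} is negative")
        object.__setattr__(self, "concentrations", conc)


@dataclass(frozen=True)
class SorptionParams:
    """First-order sorption parameters of one component in one film.

    Parameters
    ----------
    partition:
        Dimensionless partition coefficient ``K`` (>= 0); the equilibrium
        sorbed quantity is ``K * c`` for gas-phase concentration ``c``.
    tau_s:
        Sorption time constant in seconds (> 0).
    responsivity:
        Fractional resistance change per unit sorbed quantity (signed).
    """

    partition: float
    tau_s: float
    responsivity: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.partition) or self.partition < 0:
            raise ValueError("partition coefficient must be finite and >= 0")
        if not math.isfinite(self.tau_s) or self.tau_s <= 0:
            raise ValueError("sorption time constant must be finite and > 0")
        if not math.isfinite(self.responsivity):
            raise ValueError("responsivity must be finite")


@dataclass(frozen=True)
class ReceptorFilm:
    """One coated sensor channel (e.g. PPPO or PS) with per-component kinetics.

    Components referenced by a source but absent from ``components`` default
    to ``K = 0`` (no sorption, no response).
    """

    name: str
    components: Mapping[str, SorptionParams]
    tau_bounds_s: tuple[float, float] = (0.05, 200.0)

    def __post_init__(self) -> None:
        comps = dict(self.components)
        lo, hi = self.tau_bounds_s
        for comp, p in comps.items():
            if not (lo <= p.tau_s <= hi):
                raise ValueError(
                    f"film {self.name!r}: tau of {comp!r} ({p.tau_s} s) outside "
                    f"admissible range [{lo}, {hi}] s"
                )
        object.__setattr__(self, "components", comps)


@dataclass(frozen=True)
class InjectionProgram:
    """Ordered valve schedule with sampling metadata.

    ``segments`` is a sequence of ``(source_id, duration_s)`` pairs tiling
    ``[0, total_duration_s]`` exactly; each duration must be an integer
    multiple of the sampling period.  ``flow_rate_ml_min`` is carried as
    metadata only (the model has no flow dynamics).
    """

    segments: tuple[tuple[str, float], ...]
    sampling_rate_hz: float
    total_duration_s: float
    mode: str
    flow_rate_ml_min: float = 30.0

    def __post_init__(self) -> None:
        if self.mode not in ("normal", "rdc"):
            raise ValueError(f"unknown mode {self.mode!r} (expected 'normal' or 'rdc')")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be > 0")
        if not self.segments:
            raise ValueError("injection program needs at least one segment")
        total = sum(d for _, d in self.segments)
        if abs(total - self.total_duration_s) > 1e-9:
            raise ValueError(
                f"segment durations sum to {total} s, not total_duration_s={self.total_duration_s} s"
            )
        for src, d in self.segments:
            n = d * self.sampling_rate_hz
            if abs(n - round(n)) > 1e-6:
                raise ValueError(
                    f"segment ({src!r}, {d} s) is not an integer multiple of the "
                    f"sampling period {1.0 / self.sampling_rate_hz} s"
                )
        ids = [s for s, _ in self.segments]
        if len(self.segments) > 1:
            # strict two-phase alternation with period 2
            for k, s in enumerate(ids):
                if s != ids[k % 2]:
                    raise ValueError("segments must alternate two source ids")
        if self.mode == "normal" and CARRIER_ID not in set(ids):
            raise ValueError("normal mode must alternate a sample with the carrier")

    @property
    def n_samples(self) -> int:
        """Samples on the grid t = k/f, k = 0 .. duration*f inclusive."""
        return round(self.total_duration_s * self.sampling_rate_hz) + 1


@dataclass(frozen=True)
class Undulation:
    """Single-sinusoid baseline undulation (non-Gaussian noise component)."""

    amplitude_uv: float
    frequency_hz: float
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_uv < 0:
            raise ValueError("undulation amplitude must be >= 0")
        if self.frequency_hz <= 0:
            raise ValueError("undulation frequency must be > 0")


@dataclass(frozen=True)
class NoiseModel:
    """Additive measurement imperfections; the seed is mandatory.

    ``output = clean + drift_slope * t + N(0, sigma^2) + undulation``.
    """

    seed: int
    gaussian_sigma_uv: float = 0.0
    drift_slope_uv_per_s: float = 0.0
    undulation: Undulation | None = None

    def __post_init__(self) -> None:
        if self.gaussian_sigma_uv < 0:
            raise ValueError("gaussian sigma must be >= 0")


@dataclass(frozen=True)
class BridgeConfig:
    """Wheatstone bridge readout configuration.

    ``arm_weights`` maps a scalar film strain signal ``s(t)`` to the four
    fractional resistance changes ``(dR1/R1, ..., dR4/R4) = weights * s(t)``.
    The default full-bridge pattern (+1, -1, +1, -1) yields
    ``Vout = VB * s(t)``.
    """

    bridge_voltage_v: float = -1.0
    arm_weights: tuple[float, float, float, float] = (1.0, -1.0, 1.0, -1.0)

    def __post_init__(self) -> None:
        if not math.isfinite(self.bridge_voltage_v):
            raise ValueError("bridge voltage must be finite")
        if len(self.arm_weights) != 4 or not all(math.isfinite(w) for w in self.arm_weights):
            raise ValueError("arm_weights must be four finite numbers")

    @property
    def gain(self) -> float:
        """Vout / s(t) in volts per unit strain signal."""
        w1, w2, w3, w4 = self.arm_weights
        return self.bridge_voltage_v / 4.0 * (w1 - w2 + w3 - w4)


class SensorTrace:
    """Uniformly sampled sensor output (μV) for one channel.

    Attributes
    ----------
    time:
        Sample times in seconds, strictly increasing with constant step.
    output:
        Sensor output in μV, finite, same length as ``time``.
    channel:
        Receptor film name.
    program:
        The :class:`InjectionProgram` that produced the trace, if known.
    """

    def __init__(
        self,
        time: np.ndarray,
        output: np.ndarray,
        channel: str = "",
        program: InjectionProgram | None = None,
    ) -> None:
        time = np.asarray(time, dtype=float)
        output = np.asarray(output, dtype=float)
        if time.ndim != 1 or output.ndim != 1 or time.size != output.size:
            raise ValueError("time and output must be 1-D arrays of equal length")
        if time.size < 2:
            raise ValueError("a trace needs at least two samples")
        dt = time[1] - time[0]
        if dt <= 0 or not np.allclose(np.diff(time), dt, rtol=0.0, atol=1e-9 * max(dt, 1.0)):
            raise ValueError("time must be strictly increasing with a constant step")
        if not np.all(np.isfinite(output)):
            raise ValueError("output contains non-finite samples")
        self.time = time
        self.output = output
        self.channel = channel
        self.program = program

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])

    @property
    def duration_s(self) -> float:
        return float(self.time[-1] - self.time[0])

    def __len__(self) -> int:
        return self.time.size

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SensorTrace(channel={self.channel!r}, n={len(self)}, "
            f"fs={self.sampling_rate_hz:g} Hz)"
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_protocol(
    mode: str,
    sample_ids: Iterable[str],
    interval_s: float = 5.0,
    total_duration_s: float = 120.0,
    sampling_rate_hz: float = 100.0,
    flow_rate_ml_min: float = 30.0,
) -> InjectionProgram:
    """Build the alternating valve schedule for a measurement.

    rDC mode takes two sample ids ``[S1, S2]``; injections start with Sample 2
    at t = 0 and alternate every ``interval_s``, so Sample 1 starts at
    ``interval_s, 3*interval_s, ...``.  Normal mode takes one sample id and
    alternates it with the carrier using the same schedule (carrier first at
    t = 0, mirroring an rDC run with an empty Sample-2 vial), which keeps the
    Sample-1 injection starts at the same absolute times in both modes.
    """
    ids = list(sample_ids)
    n_float = total_duration_s / interval_s
    n = round(n_float)
    if abs(n_float - n) > 1e-9 or n < 1:
        raise ValueError(
            f"interval {interval_s} s does not divide total duration {total_duration_s} s"
        )
    if mode == "rdc":
        if len(ids) != 2:
            raise ValueError("rdc mode requires exactly two sample ids")
        pattern = (ids[1], ids[0])  # start with Sample 2
    elif mode == "normal":
        if len(ids) != 1:
            raise ValueError("normal mode requires exactly one sample id")
        pattern = (CARRIER_ID, ids[0])  # carrier first; sample starts at interval_s
    else:
        raise ValueError(f"unknown mode {mode!r} (expected 'normal' or 'rdc')")
    segments = tuple((pattern[k % 2], float(interval_s)) for k in range(n))
    return InjectionProgram(
        segments=segments,
        sampling_rate_hz=float(sampling_rate_hz),
        total_duration_s=float(total_duration_s),
        mode=mode,
        flow_rate_ml_min=float(flow_rate_ml_min),
    )


def time_grid(program: InjectionProgram) -> np.ndarray:
    """Sampling grid t = k/f for k = 0 .. total_duration*f inclusive."""
    return np.arange(program.n_samples) / program.sampling_rate_hz


def _source_map(sources: Iterable[OdorSource] | Mapping[str, OdorSource]) -> dict[str, OdorSource]:
    if isinstance(sources, Mapping):
        return dict(sources)
    return {s.name: s for s in sources}


def sorbed_response(
    program: InjectionProgram,
    sources: Iterable[OdorSource] | Mapping[str, OdorSource],
    film: ReceptorFilm,
) -> dict[str, np.ndarray]:
    """Per-component sorbed quantity q_i(t) on the sampling grid.

    Each component relaxes toward its equilibrium ``K_i * c_i(t)`` with
    ``dq_i/dt = (K_i * c_i(t) - q_i) / tau_i`` and ``q_i(0) = 0``, where
    ``c_i(t)`` is the concentration delivered by the active valve segment.
    The solution is evaluated segment-wise with the exact exponential update
    ``q(t0 + dt) = K*c + (q(t0) - K*c) * exp(-dt / tau)``.
    """
    srcs = _source_map(sources)
    for src_id, _ in program.segments:
        if src_id != CARRIER_ID and src_id not in srcs:
            raise KeyError(f"program references unknown source {src_id!r}")

    t = time_grid(program)
    fs = program.sampling_rate_hz
    comps = sorted({c for s in srcs.values() for c in s.concentrations})
    out: dict[str, np.ndarray] = {}
    for comp in comps:
        q = np.zeros_like(t)
        p = film.components.get(comp)
        if p is not None and p.partition > 0:
            state = 0.0
            seg_start_t = 0.0
            idx = 0
            for src_id, dur in program.segments:
                conc = 0.0
                if src_id != CARRIER_ID:
                    conc = srcs[src_id].concentrations.get(comp, 0.0)
                target = p.partition * conc
                n_seg = round(dur * fs)
                local_t = t[idx : idx + n_seg] - seg_start_t
                q[idx : idx + n_seg] = target + (state - target) * np.exp(-local_t / p.tau_s)
                state = target + (state - target) * math.exp(-dur / p.tau_s)
                seg_start_t += dur
                idx += n_seg
            q[-1] = state  # terminal fence-post sample, end of the last segment
        out[comp] = q
    return out


def film_strain(
    program: InjectionProgram,
    sources: Iterable[OdorSource] | Mapping[str, OdorSource],
    film: ReceptorFilm,
) -> np.ndarray:
    """Scalar strain signal s(t) = sum_i g_i * q_i(t)."""
    qs = sorbed_response(program, sources, film)
    s = np.zeros(program.n_samples)
    for comp, q in qs.items():
        p = film.components.get(comp)
        if p is not None:
            s += p.responsivity * q
    return s


def transduce_bridge(strain: np.ndarray, bridge: BridgeConfig | None = None) -> np.ndarray:
    """Wheatstone-bridge readout of the strain signal, in μV.

    ``Vout = (VB/4) * (w1 - w2 + w3 - w4) * s(t)`` converted from volts to
    μV.  With the default arm pattern this is ``VB * s(t)``.
    """
    if bridge is None:
        bridge = BridgeConfig()
    strain = np.asarray(strain, dtype=float)
    if not np.all(np.isfinite(strain)):
        raise ValueError("strain signal contains non-finite samples")
    return bridge.gain * strain * 1e6


def add_noise_and_drift(trace: SensorTrace, noise: NoiseModel) -> SensorTrace:
    """Add drift, Gaussian noise and optional undulation to a clean trace.

    Identical seeds give identical traces; there is no global random state.
    """
    rng = np.random.default_rng(noise.seed)
    out = trace.output + noise.drift_slope_uv_per_s * trace.time
    if noise.gaussian_sigma_uv > 0:
        out = out + rng.normal(0.0, noise.gaussian_sigma_uv, size=len(trace))
    if noise.undulation is not None:
        u = noise.undulation
        out = out + u.amplitude_uv * np.sin(2 * np.pi * u.frequency_hz * trace.time + u.phase_rad)
    return SensorTrace(trace.time, out, channel=trace.channel, program=trace.program)


def simulate_measurement(
    sources: Iterable[OdorSource] | Mapping[str, OdorSource],
    film: ReceptorFilm,
    program: InjectionProgram,
    bridge: BridgeConfig | None = None,
    noise: NoiseModel | None = None,
) -> SensorTrace:
    """Full forward model: kinetics, bridge transduction, then noise.

    With ``noise=None`` the returned trace is the noise-free model output
    (used by closed-form oracles); otherwise the trace is deterministic given
    the noise model's seed.
    """
    s = film_strain(program, sources, film)
    out = transduce_bridge(s, bridge)
    trace = SensorTrace(time_grid(program), out, channel=film.name, program=program)
    if noise is not None:
        trace = add_noise_and_drift(trace, noise)
    return trace
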