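"""Desk-scale synthetic reproduction of a two-odor comparison study.

The generated experiment mimics the canonical design for validating the rDC
protocol: two odor sources that share dominant base components (humidity and
bulk VOCs) and differ only in a minor flavor component each, measured on two
receptor channels with contrasting sorption kinetics, with six replicate sets
of {normal-A, normal-B, rDC(A, B)} measurements.  The component
concentrations and film parameters are not calibrated to any real chemistry;
they are chosen to place the simulation in the regime where interfering
gases dominate the raw response and the flavor difference is a minor signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .analyze import (
    AnalysisWindow,
    MeasurementSummary,
    analyze_trace,
    difference_trace,
    propagate_difference_noise,
    snr_summary,
)
from .simulate import (
    BridgeConfig,
    InjectionProgram,
    NoiseModel,
    OdorSource,
    ReceptorFilm,
    SensorTrace,
    SorptionParams,
    Undulation,
    build_protocol,
    simulate_measurement,
)

__all__ = [
    "ExperimentDesign",
    "default_design",
    "generate_experiment",
    "simulate_experiment",
    "run_study",
    "StudyResult",
]

#: Protocol labels of one replicate set, in generation order.
PROTOCOLS = ("normal-a", "normal-b", "rdc")


@dataclass(frozen=True)
class ExperimentDesign:
    """Everything needed to regenerate a synthetic study bit-identically."""

    source_a: OdorSource
    source_b: OdorSource
    films: tuple[ReceptorFilm, ...]
    bridge: BridgeConfig = BridgeConfig()
    gaussian_sigma_uv: float = 2.0
    drift_slope_uv_per_s: float = 0.05
    undulation: Undulation | None = None
    replicates: int = 6
    base_seed: int = 0
    interval_s: float = 5.0
    total_duration_s: float = 120.0
    sampling_rate_hz: float = 100.0
    window: AnalysisWindow = AnalysisWindow()
    cycle_duration_s: float = 10.0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        shared = set(self.source_a.concentrations) & set(self.source_b.concentrations)
        distinct = (
            set(self.source_a.concentrations) ^ set(self.source_b.concentrations)
        )
        if shared and distinct:
            lo_shared = min(self.source_a.concentrations.get(c, math.inf) for c in shared)
            hi_distinct = max(
                {**self.source_a.concentrations, **self.source_b.concentrations}[c]
                for c in distinct
            )
            if lo_shared <= hi_distinct:
                raise ValueError(
                    "shared (interfering) component concentrations must exceed the "
                    "distinct flavor component concentrations"
                )

    def seed_table(self) -> dict[tuple[int, str, str], int]:
        """Deterministic, pairwise-distinct seed per (replicate, protocol, channel)."""
        keys = [
            (rep, proto, film.name)
            for rep in range(self.replicates)
            for proto in PROTOCOLS
            for film in self.films
        ]
        children = np.random.SeedSequence(self.base_seed).spawn(len(keys))
        seeds = {k: int(c.generate_state(1)[0]) for k, c in zip(keys, children)}
        if len(set(seeds.values())) != len(seeds):
            raise ValueError("seed collision in the replicate seed schedule")
        return seeds


def default_design(base_seed: int = 0, replicates: int = 6) -> ExperimentDesign:
    """The default study: two similar food-like odors on two channels.

    Both sources share a dominant humidity component (concentration 100) and
    two base VOCs (10 each); each adds one distinct flavor component
    (vanillin-like in A, furaneol-like in B) at concentration 1.  The PPPO
    channel is the stronger sorbent with a preference for the A flavor; the
    PS channel is slower overall with a preference for the B flavor, so the
    two channels exercise the protocol with signed, channel-dependent
    difference signals.  Sorption time constants span 0.5–20 s, inside the
    0.1–100 s range typical of polymer receptor films.  Responsivities are
    negative so that, with the −1 V bridge bias, sorption drives the output
    positive.
    """
    source_a = OdorSource(
        "sample_a",
        {"humidity": 100.0, "base_voc_1": 10.0, "base_voc_2": 10.0, "flavor_a": 1.0},
    )
    source_b = OdorSource(
        "sample_b",
        {"humidity": 100.0, "base_voc_1": 10.0, "base_voc_2": 10.0, "flavor_b": 1.0},
    )
    pppo = ReceptorFilm(
        "PPPO",
        {
            "humidity": SorptionParams(partition=1.0, tau_s=2.0, responsivity=-6e-7),
            "base_voc_1": SorptionParams(partition=2.0, tau_s=0.5, responsivity=-4e-7),
            "base_voc_2": SorptionParams(partition=1.5, tau_s=8.0, responsivity=-3e-7),
            "flavor_a": SorptionParams(partition=5.0, tau_s=1.0, responsivity=-2e-6),
            "flavor_b": SorptionParams(partition=2.0, tau_s=0.6, responsivity=-8e-7),
        },
    )
    ps = ReceptorFilm(
        "PS",
        {
            "humidity": SorptionParams(partition=0.5, tau_s=4.0, responsivity=-4e-7),
            "base_voc_1": SorptionParams(partition=1.0, tau_s=20.0, responsivity=-6e-7),
            "base_voc_2": SorptionParams(partition=1.0, tau_s=1.5, responsivity=-2e-7),
            "flavor_a": SorptionParams(partition=3.0, tau_s=2.0, responsivity=-1e-6),
            "flavor_b": SorptionParams(partition=6.0, tau_s=0.8, responsivity=-3e-6),
        },
    )
    return ExperimentDesign(
        source_a=source_a,
        source_b=source_b,
        films=(pppo, ps),
        base_seed=base_seed,
        replicates=replicates,
    )


def _programs(design: ExperimentDesign) -> dict[str, InjectionProgram]:
    kw = dict(
        interval_s=design.interval_s,
        total_duration_s=design.total_duration_s,
        sampling_rate_hz=design.sampling_rate_hz,
    )
    return {
        "normal-a": build_protocol("normal", [design.source_a.name], **kw),
        "normal-b": build_protocol("normal", [design.source_b.name], **kw),
        "rdc": build_protocol("rdc", [design.source_a.name, design.source_b.name], **kw),
    }


def simulate_experiment(
    design: ExperimentDesign,
) -> dict[tuple[int, str, str], SensorTrace]:
    """Simulate every trace of the study, keyed by (replicate, protocol, channel)."""
    sources = {design.source_a.name: design.source_a, design.source_b.name: design.source_b}
    programs = _programs(design)
    seeds = design.seed_table()
    traces: dict[tuple[int, str, str], SensorTrace] = {}
    for (rep, proto, channel), seed in seeds.items():
        film = next(f for f in design.films if f.name == channel)
        noise = NoiseModel(
            seed=seed,
            gaussian_sigma_uv=design.gaussian_sigma_uv,
            drift_slope_uv_per_s=design.drift_slope_uv_per_s,
            undulation=design.undulation,
        )
        traces[(rep, proto, channel)] = simulate_measurement(
            sources, film, programs[proto], design.bridge, noise
        )
    return traces


def generate_experiment(design: ExperimentDesign, out_dir: str | Path) -> pd.DataFrame:
    """Write every trace as CSV plus a manifest; returns the manifest.

    Output is ``replicates x 3 protocols x channels`` trace files named
    ``rep<k>_<protocol>_<channel>.csv`` and ``manifest.csv`` mapping each
    file to its replicate, protocol, channel and noise seed.  Regeneration
    with the same design is bit-identical.
    """
    from .io import write_trace  # local import to avoid a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = design.seed_table()
    traces = simulate_experiment(design)
    rows = []
    for (rep, proto, channel), trace in traces.items():
        fname = f"rep{rep}_{proto}_{channel}.csv"
        write_trace(trace, out_dir / fname)
        rows.append(
            {
                "filename": fname,
                "replicate": rep,
                "protocol": proto,
                "channel": channel,
                "seed": seeds[(rep, proto, channel)],
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


@dataclass(frozen=True)
class StudyResult:
    """Per-measurement summaries and their replicate-level aggregation."""

    summaries: list[MeasurementSummary]
    table: pd.DataFrame

    def mean(self, channel: str, measurement_type: str, fieldname: str) -> float:
        row = self.table[
            (self.table.channel == channel)
            & (self.table.measurement_type == measurement_type)
        ]
        return float(row[f"{fieldname}_mean"].iloc[0])


def run_study(design: ExperimentDesign) -> StudyResult:
    """Run the full study end to end and aggregate the statistics.

    For every replicate and channel this analyzes the rDC trace and the
    pointwise difference of the two normal traces (sample B minus sample A).
    The theoretical noise of the difference is propagated in quadrature from
    the two normal measurements' theoretical noise levels.  The returned
    table has one row per (channel, measurement type) with mean and sample
    standard deviation of intensity, noise and S/N across replicates —
    per-replicate S/N is computed before aggregation.
    """
    traces = simulate_experiment(design)
    kw = dict(
        window=design.window,
        cycle_duration_s=design.cycle_duration_s,
    )
    per_type: dict[tuple[str, str], list[MeasurementSummary]] = {}
    all_summaries: list[MeasurementSummary] = []
    for rep in range(design.replicates):
        for film in design.films:
            ch = film.name
            s_na = analyze_trace(traces[(rep, "normal-a", ch)], measurement_type="normal", **kw)
            s_nb = analyze_trace(traces[(rep, "normal-b", ch)], measurement_type="normal", **kw)
            s_rdc = analyze_trace(traces[(rep, "rdc", ch)], measurement_type="rdc", **kw)
            diff = difference_trace(
                traces[(rep, "normal-b", ch)], traces[(rep, "normal-a", ch)]
            )
            s_diff = analyze_trace(diff, measurement_type="difference", **kw)
            s_diff = replace(
                s_diff,
                noise_theory_uv=propagate_difference_noise(
                    s_na.noise_theory_uv, s_nb.noise_theory_uv
                ),
            )
            all_summaries.extend((s_na, s_nb, s_rdc, s_diff))
            # the aggregated table compares the two difference-type methods
            for s in (s_rdc, s_diff):
                per_type.setdefault((ch, s.measurement_type), []).append(s)
    rows = []
    for (ch, mtype), summaries in sorted(per_type.items()):
        if len(summaries) >= 2:
            stats = snr_summary(summaries)
            row: dict[str, object] = {"channel": ch, "measurement_type": mtype}
            for fieldname in stats.index:
                row[f"{fieldname}_mean"] = stats.loc[fieldname, "mean"]
                row[f"{fieldname}_std"] = stats.loc[fieldname, "std"]
            rows.append(row)
    return StudyResult(summaries=all_summaries, table=pd.DataFrame(rows))
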