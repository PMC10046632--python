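import numpy as np
import pytest

from rdcsense.simulate import (
    OdorSource,
    ReceptorFilm,
    SensorTrace,
    SorptionParams,
    build_protocol,
)


@pytest.fixture
def single_component_setup():
    """One component, one source, one film — closed-form oracle territory."""
    source = OdorSource("sample", {"x": 2.0})
    film = ReceptorFilm(
        "chan",
        {"x": SorptionParams(partition=1.5, tau_s=0.1, responsivity=-1e-6)},
    )
    return source, film


@pytest.fixture
def rdc_program():
    return build_protocol("rdc", ["s1", "s2"], 5.0, 120.0, 100.0)


def make_trace(output, fs=100.0, channel="chan", program=None):
    output = np.asarray(output, dtype=float)
    return SensorTrace(np.arange(output.size) / fs, output, channel=channel, program=program)


@pytest.fixture
def periodic_trace():
    """A 120 s, 100 Hz trace that is bit-exactly 10 s-periodic (sawtooth)."""
    t = np.arange(12001) / 100.0
    period = np.arange(1000) / 100.0
    return SensorTrace(t, np.resize(period, 12001), channel="saw")
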