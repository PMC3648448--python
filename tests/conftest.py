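"""Shared fixtures: small geometries, phantoms and simulated streams."""

import numpy as np
import pytest

from petgate import simdata
from petgate.geometry import ScannerGeometry


@pytest.fixture(scope="session")
def small_geom() -> ScannerGeometry:
    return ScannerGeometry.small()


@pytest.fixture(scope="session")
def moving_stream(small_geom):
    """1-minute rat-like scan with 1 Hz breathing, 1e6 events."""
    waveform = simdata.make_waveform(1.0, 0.05, 60.0, seed=0)
    phantom = simdata.make_rat_phantom(small_geom)
    stream = simdata.sample_events(
        phantom, waveform, 1.0e6, 60.0, seed=0, geometry=small_geom
    )
    return stream, waveform


@pytest.fixture(scope="session")
def static_stream(small_geom):
    """1-minute static scan (no moving structures), 2e5 events."""
    phantom = simdata.make_rat_phantom(small_geom, motion_amplitude_mm=0.0)
    phantom.structures = [s.__class__(s.shape, s.activity) for s in phantom.structures]
    waveform = simdata.make_waveform(1.0, 0.05, 60.0, seed=1)
    return simdata.sample_events(
        phantom, waveform, 2.0e5, 60.0, seed=1, geometry=small_geom
    ), waveform


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
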