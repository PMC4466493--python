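import numpy as np
import pytest

import rpewave as rw


@pytest.fixture(scope="session")
def geom():
    return rw.CellGeometry()


@pytest.fixture(scope="session")
def params():
    return rw.ModelParams()


@pytest.fixture(scope="session")
def stim():
    return rw.StimulusParams()


@pytest.fixture(scope="session")
def ga_traces(geom, params, stim):
    """Full 90-s uncoupled-monolayer simulation, shared across tests."""
    return rw.simulate("GA_treated", params, geom, stim)


@pytest.fixture(scope="session")
def control_traces(geom, params, stim):
    """Full 90-s control (gap junctions open) simulation, shared across tests."""
    return rw.simulate("control", params, geom, stim)
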