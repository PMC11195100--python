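import numpy as np
import pytest
from hypothesis import settings

import kndysim as ks

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ovx():
    return ks.load_preset("ovx")


@pytest.fixture(scope="session")
def ovx_e2():
    return ks.load_preset("ovx_e2")


@pytest.fixture(scope="session")
def leak_only(ovx):
    """A passive cell: every conductance but leak removed."""
    p = ovx.copy()
    for name, ch in p.channels.items():
        if name != "leak":
            ch.gbar = 0.0
    p.state_label = "custom"
    return p


@pytest.fixture(scope="session")
def e2_spontaneous(ovx_e2):
    """One 20-s spontaneous OVX+E2 trace shared across tests."""
    return ks.simulate(ovx_e2, ks.spontaneous_protocol(20.0))


def spike_count(trace):
    return ks.spike_times(trace).size
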