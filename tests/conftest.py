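"""Shared fixtures: a small 4x4 layout and one simulated recording.

Session-scoped because the discharge simulation is the slowest shared step;
every test treats the fixtures as read-only.
"""

import numpy as np
import pytest

from pdcnet import preprocess as pre
from pdcnet import synthetic as syn


@pytest.fixture(scope="session")
def small_layout():
    return syn.make_mea_layout(n_rows=4, n_cols=4, pcl_rows=(1,), gcl_rows=(2,))


@pytest.fixture(scope="session")
def small_net(small_layout):
    return syn.default_ground_truth(small_layout, gain=0.8)


@pytest.fixture(scope="session")
def sim_config():
    return syn.SimulationConfig(n_events=12, seed=7)


@pytest.fixture(scope="session")
def sim_recording(small_layout, small_net, sim_config):
    rec, events = syn.simulate_discharge_recording(small_layout, small_net, sim_config)
    return rec, events


@pytest.fixture(scope="session")
def detected_times(small_layout, sim_recording):
    rec, _ = sim_recording
    ref = int(small_layout.nodes_in_layer("pcl")[0])
    return pre.detect_events(rec, ref)


@pytest.fixture(scope="session")
def short_ensemble(sim_recording, detected_times):
    """Conditioned 800 ms ensemble (300 pre / 500 post)."""
    rec, _ = sim_recording
    ens = pre.extract_segments(rec, detected_times, pre_ms=300, post_ms=500)
    return pre.condition_ensemble(ens)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
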