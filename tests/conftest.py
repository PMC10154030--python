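import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from flockspread.network_builder import SocialNetwork

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_network(n, edges, network_id="net", location_id="L00", year=2012, week=1):
    """Build a SocialNetwork from {(i, j): weight} on nodes n0..n{n-1}."""
    w = np.zeros((n, n))
    for (i, j), weight in edges.items():
        w[i, j] = w[j, i] = weight
    return SocialNetwork(
        network_id=network_id,
        location_id=location_id,
        year=year,
        week=week,
        nodes=[f"n{k}" for k in range(n)],
        weights=w,
    )


def complete_network(n, weight=0.5, **kw):
    return make_network(
        n, {(i, j): weight for i in range(n) for j in range(i + 1, n)}, **kw
    )


@pytest.fixture
def triangle():
    return make_network(3, {(0, 1): 0.5, (0, 2): 0.5, (1, 2): 0.5})


@pytest.fixture
def star5():
    """Centre n0 with 4 spokes of weight 0.25."""
    return make_network(5, {(0, k): 0.25 for k in range(1, 5)})


@pytest.fixture
def path4():
    """Line n0-n1-n2-n3 with unit weights."""
    return make_network(4, {(0, 1): 1.0, (1, 2): 1.0, (2, 3): 1.0})


@pytest.fixture(scope="session")
def small_batch():
    """A small filtered batch of synthetic networks with node metrics."""
    from flockspread import FlockGenConfig, generate_flock_events
    from flockspread.network_builder import build_networks, filter_networks
    from flockspread.metrics import node_metrics

    config = FlockGenConfig(n_locations=4, n_periods=6, seed=42)
    events = generate_flock_events(config)
    nets, _ = filter_networks(build_networks(events))
    metrics = {net.network_id: node_metrics(net) for net in nets}
    return nets, metrics
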