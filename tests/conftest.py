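"""Shared fixtures and graph builders for the test suite."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from cityaccess import CitySpec, RoadNetwork, fig2_fixture, generate_city


def random_road_graph(n_nodes: int, seed: int, p: float = 0.25) -> RoadNetwork:
    """A random connected graph with small-integer edge travel times.

    Integer minute weights keep shortest-path sums exact in floating point, so
    independently computed all-pairs results can be compared for equality.
    Node coordinates are random but irrelevant to routing.
    """
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(2**31)))
    # force connectivity with a random spanning chain
    order = rng.permutation(n_nodes)
    for a, b in zip(order, order[1:]):
        g.add_edge(int(a), int(b))
    h = nx.Graph()
    for node in g.nodes:
        h.add_node(str(node), x=float(rng.uniform(0, 1000)), y=float(rng.uniform(0, 1000)))
    for u, v in g.edges:
        t = int(rng.integers(1, 10))
        h.add_edge(
            str(u), str(v),
            travel_time=float(t),
            length=float(t * 500),
            speed=30.0,
            road_class="local",
            geometry=None,
        )
    return RoadNetwork(h)


@pytest.fixture
def fig2():
    """The hand-coded illustrative city (network, cells, amenities, hazards)."""
    return fig2_fixture()


@pytest.fixture
def small_city():
    """A deterministic 5x5 lattice city with 3 facilities."""
    spec = CitySpec(rows=5, cols=5, n_facilities=3, seed=42)
    return generate_city(spec)
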