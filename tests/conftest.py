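"""Shared fixtures: published worked-example networks and a random-net factory."""

from __future__ import annotations

import numpy as np
import pytest

from acenet.ego_network import DirectedEgoNetwork


@pytest.fixture()
def fig_reciprocity_net() -> DirectedEgoNetwork:
    """Worked reciprocity example: 5 followers, 6 followees, 2 reciprocal."""
    followers = {"f1", "f2", "f3", "f4", "f5"}
    # the two reciprocal neighbors f1, f2 are also among the root's followees
    followees = {"f1", "f2", "g1", "g2", "g3", "g4"}
    edges = {(f, "u") for f in followers}
    edges |= {("u", g) for g in followees}
    return DirectedEgoNetwork(
        root="u", followers=followers, followees=followees, edges=edges
    )


@pytest.fixture()
def fig_homophily_net() -> tuple[DirectedEgoNetwork, dict[str, float]]:
    """Worked homophily example: 3 followers (0.5/0.6/0.7), 4 followees
    (0.3/0.6/0.7/0.4); the 0.6 and 0.7 followers are reciprocal."""
    followers = {"f1", "f2", "f3"}
    followees = {"f2", "f3", "g1", "g2"}
    edges = {(f, "u") for f in followers} | {("u", g) for g in followees}
    net = DirectedEgoNetwork(
        root="u", followers=followers, followees=followees, edges=edges
    )
    alpha = {"f1": 0.5, "f2": 0.6, "f3": 0.7, "g1": 0.3, "g2": 0.4}
    return net, alpha


def random_ego_network(
    rng: np.random.Generator, max_nodes: int = 15
) -> DirectedEgoNetwork:
    """A random sampled ego network over at most ``max_nodes`` nodes.

    Follower and followee sets may overlap; extra directed edges among
    neighbors appear with random density.
    """
    n_neighbors = int(rng.integers(0, max_nodes))  # excludes the root
    nodes = [f"v{i}" for i in range(n_neighbors)]
    followers = {v for v in nodes if rng.random() < 0.6}
    followees = {v for v in nodes if rng.random() < 0.6}
    edges = {(f, "u") for f in followers} | {("u", g) for g in followees}
    for a in nodes:
        for b in nodes:
            if a != b and rng.random() < 0.3:
                edges.add((a, b))
    return DirectedEgoNetwork(
        root="u", followers=followers, followees=followees, edges=edges
    )
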