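"""Shared fixtures: seeded RNG and random-tree generators."""

from __future__ import annotations

import numpy as np
import pytest

from nestshift.tree import Node, RootedTree


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_tree(
    rng: np.random.Generator, n: int, polytomy_prob: float = 0.0
) -> RootedTree:
    """Random rooted tree over n labeled leaves by uniform joins.

    With polytomy_prob > 0, some joins merge three or more subtrees,
    producing polytomies.
    """
    nodes = [Node(label=f"t{i}") for i in range(n)]
    while len(nodes) > 1:
        take = 2
        if polytomy_prob > 0 and len(nodes) > 2 and rng.random() < polytomy_prob:
            take = min(int(rng.integers(3, 5)), len(nodes))
        idx = rng.choice(len(nodes), size=take, replace=False)
        parent = Node()
        for i in sorted(idx, reverse=True):
            parent.add_child(nodes.pop(i))
        nodes.append(parent)
    return RootedTree(nodes[0])


@pytest.fixture
def random_tree_factory():
    return random_tree
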