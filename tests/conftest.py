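"""Shared fixtures and tiny random-structure helpers."""

from __future__ import annotations

import numpy as np
import pytest

from traitrad.tree import Node, Tree


def random_rooted_tree(rng: np.random.Generator, n_tips: int,
                       max_bl: float = 1.0, labels=None) -> Tree:
    """Random rooted binary tree by sequential joins, random lengths."""
    if labels is None:
        labels = [f"t{i}" for i in range(n_tips)]
    nodes = [Node(label=lab, length=float(rng.uniform(0.05, max_bl)))
             for lab in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = Node(length=float(rng.uniform(0.05, max_bl)))
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    root = Node()
    for n in nodes:
        root.add_child(n)
    return Tree(root, rooted=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_scenario():
    """A compact synthetic scenario shared by fast tests."""
    from traitrad.simulate import ScenarioConfig, generate_scenario
    return generate_scenario(ScenarioConfig(seed=5, n_species=16))
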