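"""Shared fixtures: the worked 4-leaf tree and random-tree fuzzers."""

from __future__ import annotations

import numpy as np
import pytest

from rhodate.genealogy import Genealogy, Node, read_tree

# 4-leaf worked example: edges root->A (R=1, 3 leaves below), A->L1 (0),
# A->L2 (0), A->L3 (1), root->L4 (0).  L = [1, 1, 2, 0], rho = 1.
WORKED_NEWICK = "((L1:0,L2:0,L3:1)A:1,L4:0)root;"

# the same topology made ultrametric (TMRCA 100 generations)
WORKED_NEWICK_TIMES = "((L1:40,L2:40,L3:40)A:60,L4:100)root;"


@pytest.fixture
def worked_tree() -> Genealogy:
    return read_tree(WORKED_NEWICK, "mutations")


@pytest.fixture
def worked_tree_times() -> Genealogy:
    return read_tree(WORKED_NEWICK_TIMES, "times")


def random_genealogy(rng: np.random.Generator, max_leaves: int = 12) -> Genealogy:
    """A random multifurcating mutation-annotated genealogy.

    Leaves are merged bottom-up in random groups of 2-4, so topologies
    include polytomies; edge mutation counts are Poisson(1.2).
    """
    n = int(rng.integers(1, max_leaves + 1))
    nodes: list[Node] = [Node(label=f"L{i}") for i in range(n)]
    if n == 1:
        root = Node(label="root", children=nodes)
    else:
        while len(nodes) > 1:
            k = min(len(nodes), int(rng.integers(2, 5)))
            picks = sorted(rng.choice(len(nodes), size=k, replace=False))
            children = [nodes[i] for i in picks]
            for i in reversed(picks):
                del nodes[i]
            nodes.append(Node(children=children))
        root = nodes[0]
    g = Genealogy(root)
    for edge in g.edges:
        edge.mutations = int(rng.poisson(1.2))
    return Genealogy(root)  # re-validate with annotations


def star_genealogy(rng: np.random.Generator, n: int = 8) -> Genealogy:
    """Star tree: every leaf attached directly to the root."""
    leaves = [
        Node(label=f"L{i}", mutations=int(rng.poisson(2.0))) for i in range(n)
    ]
    return Genealogy(Node(label="root", children=leaves))
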