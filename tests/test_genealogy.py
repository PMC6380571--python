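"""Genealogy data model, newick dialects and structural queries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhodate.genealogy import (
    Genealogy,
    GenealogyError,
    Node,
    edge_leaf_counts,
    haplotype_partition,
    leaf_path_counts,
    read_tree,
    tmrca_from_times,
    write_tree,
)

from conftest import WORKED_NEWICK, random_genealogy


class TestReadTree:
    def test_mutations_dialect(self):
        g = read_tree("(A:1,B:1):0;", "mutations")
        assert g.n_leaves == 2
        assert sorted(e.mutations for e in g.edges) == [1, 1]
        assert not g.has_times

    def test_times_dialect_is_ultrametric(self):
        g = read_tree("(A:100,B:100):0;", "times")
        assert g.has_times
        assert tmrca_from_times(g) == pytest.approx(100.0)
        # times dialect initialises mutation counts to zero
        assert all(e.mutations == 0 for e in g.edges)

    @pytest.mark.parametrize(
        "text, dialect",
        [
            ("(A:1.5,B:1):0;", "mutations"),  # non-integer count
            ("(A:-1,B:1):0;", "mutations"),  # negative length
            ("(A:1,B):0;", "mutations"),  # missing branch length
            ("(A:100,B:90):0;", "times"),  # non-ultrametric
            ("[&U](A:1,B:1):0;", "mutations"),  # explicitly unrooted
        ],
    )
    def test_invalid_inputs(self, text, dialect):
        with pytest.raises(GenealogyError):
            read_tree(text, dialect)

    def test_round_flag_accepts_near_integers(self):
        with pytest.raises(GenealogyError):
            read_tree("(A:1.0000004,B:1):0;", "mutations")
        g = read_tree("(A:1.0000004,B:1):0;", "mutations", round_mutations=True)
        assert sorted(e.mutations for e in g.edges) == [1, 1]

    def test_unknown_dialect(self):
        with pytest.raises(ValueError):
            read_tree("(A:1,B:1):0;", "branchlengths")

    def test_duplicate_leaf_labels_rejected(self):
        with pytest.raises(GenealogyError):
            read_tree("(A:1,A:2):0;", "mutations")


class TestWriteTree:
    def test_mutations_round_trip_preserves_edge_multiset(self):
        g = read_tree(WORKED_NEWICK, "mutations")
        g2 = read_tree(write_tree(g, "mutations"), "mutations")
        assert sorted(e.mutations for e in g.edges) == sorted(
            e.mutations for e in g2.edges
        )
        assert leaf_path_counts(g) == leaf_path_counts(g2)

    def test_times_round_trip_preserves_path_sums(self):
        g = read_tree("((A:50,B:50):50,C:100):0;", "times")
        g2 = read_tree(write_tree(g, "times"), "times")
        assert tmrca_from_times(g2) == pytest.approx(
            tmrca_from_times(g), rel=1e-9
        )

    def test_missing_annotation_errors(self):
        g = read_tree("(A:1,B:1):0;", "mutations")
        with pytest.raises(GenealogyError):
            write_tree(g, "times")

    def test_random_trees_round_trip(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            g = random_genealogy(rng)
            g2 = read_tree(write_tree(g, "mutations"), "mutations")
            assert leaf_path_counts(g) == leaf_path_counts(g2)
            assert sorted(e.mutations for e in g.edges) == sorted(
                e.mutations for e in g2.edges
            )


class TestLeafPathCounts:
    def test_worked_tree(self, worked_tree):
        assert leaf_path_counts(worked_tree) == {"L1": 1, "L2": 1, "L3": 2, "L4": 0}

    def test_all_zero(self):
        g = read_tree("((A:0,B:0):0,C:0):0;", "mutations")
        assert set(leaf_path_counts(g).values()) == {0}

    def test_single_leaf_single_edge(self):
        g = Genealogy(Node(label="root", children=[Node(label="leaf", mutations=3)]))
        assert leaf_path_counts(g) == {"leaf": 3}


class TestEdgeLeafCounts:
    def test_worked_tree(self, worked_tree):
        by_label = {
            node.label or "A": c
            for node, c in edge_leaf_counts(worked_tree).items()
        }
        assert by_label == {"A": 3, "L1": 1, "L2": 1, "L3": 1, "L4": 1}

    def test_star_and_two_leaf_trees_all_one(self):
        for text in ["(A:1,B:2,C:0,D:1)r;", "(A:1,B:1):0;"]:
            g = read_tree(text, "mutations")
            assert set(edge_leaf_counts(g).values()) == {1}

    def test_root_children_counts_sum_to_n(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            g = random_genealogy(rng)
            nj = edge_leaf_counts(g)
            assert sum(nj[c] for c in g.root.children) == g.n_leaves


class TestTmrcaFromTimes:
    def test_nested_ultrametric(self):
        g = read_tree("((A:50,B:50):50,C:100):0;", "times")
        assert tmrca_from_times(g) == pytest.approx(100.0)

    def test_times_absent_errors(self, worked_tree):
        with pytest.raises(GenealogyError):
            tmrca_from_times(worked_tree)


class TestHaplotypePartition:
    def test_worked_tree(self, worked_tree):
        part = haplotype_partition(worked_tree)
        blocks = {
            tuple(sorted(b.labels)): (b.multiplicity, b.root_distance)
            for b in part.blocks
        }
        assert blocks == {
            ("L1", "L2"): (2, 1),
            ("L3",): (1, 2),
            ("L4",): (1, 0),
        }

    def test_no_mutations_single_block(self):
        g = read_tree("((A:0,B:0):0,C:0,D:0):0;", "mutations")
        part = haplotype_partition(g)
        assert len(part.blocks) == 1
        assert part.blocks[0].multiplicity == 4
        assert part.blocks[0].root_distance == 0

    def test_star_all_singletons(self):
        g = read_tree("(A:1,B:1,C:1)r;", "mutations")
        part = haplotype_partition(g)
        assert sorted(b.multiplicity for b in part.blocks) == [1, 1, 1]
        assert all(b.root_distance == 1 for b in part.blocks)

    def test_adding_mutations_refines_partition(self):
        """Extra mutations can split haplotype blocks but never merge them."""
        rng = np.random.default_rng(11)
        for _ in range(30):
            g = random_genealogy(rng)
            before = {frozenset(b.labels) for b in haplotype_partition(g).blocks}
            edge = g.edges[int(rng.integers(0, g.n_edges))]
            edge.mutations += 1
            after = {frozenset(b.labels) for b in haplotype_partition(g).blocks}
            for block in after:
                assert any(block <= old for old in before)


# -- the exact mutation-accounting identity, fuzzed over tree shapes --------

_tree_structure = st.recursive(
    st.integers(min_value=0, max_value=3),
    lambda kids: st.tuples(
        st.integers(min_value=0, max_value=3),
        st.lists(kids, min_size=2, max_size=4),
    ),
    max_leaves=15,
)


def _build(structure, counter=None) -> Node:
    if counter is None:
        counter = iter(range(10_000))
    if isinstance(structure, int):
        return Node(label=f"L{next(counter)}", mutations=structure)
    r, children = structure
    return Node(mutations=r, children=[_build(c, counter) for c in children])


@given(st.lists(_tree_structure, min_size=2, max_size=4))
@settings(derandomize=True, max_examples=60, deadline=None)
def test_total_path_counts_equal_edge_weighted_counts(children):
    """sum_i L_i == sum_j n_j R_j: each mutation counted once per leaf below."""
    counter = iter(range(10_000))
    g = Genealogy(Node(label="root", children=[_build(c, counter) for c in children]))
    L = leaf_path_counts(g)
    nj = edge_leaf_counts(g)
    assert sum(L.values()) == sum(c * node.mutations for node, c in nj.items())
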