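"""Rooted mutation-annotated genealogies.

The central object is :class:`Genealogy`: a rooted (possibly
multifurcating) tree whose root is the most recent common ancestor
(MRCA) of the sampled sequences.  Each edge ``j`` may carry

* an integer mutation count ``R_j`` — the number of mutations that
  occurred on that lineage segment under the infinite-sites model, and/or
* a time length ``T_j`` in generations.

Trees are read from and written to newick text in one of two dialects:
``mutations`` (branch-length field holds the integer mutation count) or
``times`` (branch-length field holds the time length in generations; a
tree with times must be ultrametric, i.e. every root-to-leaf path sums
to the same total ``T``, the time to the MRCA).

Edges are identified by their child node throughout: maps keyed "per
edge" use the child :class:`Node` as the key.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "Node",
    "Genealogy",
    "HaplotypeBlock",
    "HaplotypePartition",
    "read_tree",
    "write_tree",
    "leaf_path_counts",
    "edge_leaf_counts",
    "tmrca_from_times",
    "haplotype_partition",
    "GenealogyError",
]

#: relative tolerance for the ultrametricity check on timed trees
ULTRAMETRIC_RTOL = 1e-9

#: absolute tolerance used when the mutations dialect permits rounding
MUTATION_ROUND_ATOL = 1e-6


class GenealogyError(ValueError):
    """Raised on structurally or numerically invalid genealogies."""


class Node:
    """A tree node; ``mutations`` and ``time`` annotate the edge above it.

    The root's ``mutations``/``time`` are ``None`` (there is no edge
    above the MRCA).
    """

    __slots__ = ("label", "children", "mutations", "time")

    def __init__(self, label=None, children=None, mutations=None, time=None):
        self.label = label
        self.children = list(children) if children is not None else []
        self.mutations = mutations
        self.time = time

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} R={self.mutations} T={self.time}>"


class Genealogy:
    """A validated rooted genealogy.

    Parameters
    ----------
    root
        Root node of the tree; interpreted as the MRCA / ancestral
        haplotype.  Every non-root node's ``mutations`` (``R_j``) and/or
        ``time`` (``T_j``) annotate the edge joining it to its parent.

    Invariants enforced at construction: all ``R_j`` are non-negative
    integers; all ``T_j`` are non-negative reals; annotations are
    all-or-none per kind across edges; timed trees are ultrametric to
    relative tolerance ``ULTRAMETRIC_RTOL``; leaf labels are unique.
    """

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- structure ----------------------------------------------------

    def preorder(self):
        """Yield nodes root-first; children in insertion order."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        """Yield nodes children-first."""
        out = list(self.preorder())
        return reversed(out)

    @property
    def leaves(self) -> list[Node]:
        return [v for v in self.preorder() if v.is_leaf]

    @property
    def edges(self) -> list[Node]:
        """Non-root nodes, each standing for the edge above it."""
        return [v for v in self.preorder() if v is not self.root]

    @property
    def n_leaves(self) -> int:
        return sum(1 for v in self.preorder() if v.is_leaf)

    @property
    def n_edges(self) -> int:
        return sum(1 for _ in self.preorder()) - 1

    @property
    def has_mutations(self) -> bool:
        return self._has_mutations

    @property
    def has_times(self) -> bool:
        return self._has_times

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        seen: set[int] = set()
        labels: set[str] = set()
        n_mut = n_time = n_edges = 0
        for node in self.preorder():
            if id(node) in seen:
                raise GenealogyError("tree contains a cycle or shared node")
            seen.add(id(node))
            if node.is_leaf:
                if node.label is None:
                    raise GenealogyError("leaf without a label")
                if node.label in labels:
                    raise GenealogyError(f"duplicate leaf label {node.label!r}")
                labels.add(node.label)
            if node is self.root:
                continue
            n_edges += 1
            if node.mutations is not None:
                r = node.mutations
                if not isinstance(r, (int,)) or isinstance(r, bool):
                    raise GenealogyError(
                        f"mutation count must be an integer, got {r!r}"
                    )
                if r < 0:
                    raise GenealogyError(f"negative mutation count {r}")
                n_mut += 1
            if node.time is not None:
                if not math.isfinite(node.time) or node.time < 0:
                    raise GenealogyError(f"invalid time length {node.time!r}")
                n_time += 1
        if n_mut not in (0, n_edges):
            raise GenealogyError("mutation counts must annotate all edges or none")
        if n_time not in (0, n_edges):
            raise GenealogyError("time lengths must annotate all edges or none")
        self._has_mutations = n_edges > 0 and n_mut == n_edges
        self._has_times = n_edges > 0 and n_time == n_edges
        if self._has_times:
            self._check_ultrametric()

    def _check_ultrametric(self) -> float:
        depths = _leaf_depths(self, "time")
        total = next(iter(depths.values()))
        for label, d in depths.items():
            if not math.isclose(d, total, rel_tol=ULTRAMETRIC_RTOL, abs_tol=1e-12):
                raise GenealogyError(
                    f"tree is not ultrametric: path to {label!r} sums to {d}, "
                    f"expected {total}"
                )
        return total


@dataclass(frozen=True)
class HaplotypeBlock:
    """One distinct haplotype: its leaves, multiplicity and root distance."""

    labels: frozenset[str]
    multiplicity: int  # f_h
    root_distance: int  # l_h, mutations from the MRCA


@dataclass
class HaplotypePartition:
    """Partition of the leaves into identical-haplotype classes."""

    blocks: list[HaplotypeBlock] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return sum(b.multiplicity for b in self.blocks)


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------


def read_tree(text: str, dialect: str, *, round_mutations: bool = False) -> Genealogy:
    """Parse a single rooted newick tree.

    Parameters
    ----------
    text
        Newick string, one tree, trailing semicolon required.
    dialect
        ``"mutations"``: branch lengths are integer mutation counts
        ``R_j``; ``"times"``: branch lengths are time lengths ``T_j`` in
        generations (mutation counts initialised to 0 so the tree is
        ready for mutation dropping).
    round_mutations
        In the mutations dialect, accept branch lengths within
        ``MUTATION_ROUND_ATOL`` of an integer and round them; otherwise
        any non-integer length is an error.  Silent rounding is off by
        default because it hides data errors.
    """
    if dialect not in ("mutations", "times"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            rooting="default-rooted",
        )
    except Exception as exc:
        raise GenealogyError(f"newick parse failure: {exc}") from exc
    if dtree.is_rooted is False:
        raise GenealogyError("unrooted input: the newick root must be the MRCA")

    def convert(dnode, is_root):
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(label=label)
        if not is_root:
            length = dnode.edge.length
            if length is None:
                raise GenealogyError(f"missing branch length above {label!r}")
            if length < 0:
                raise GenealogyError(f"negative branch length above {label!r}")
            if dialect == "mutations":
                r = round(length)
                if abs(length - r) > (MUTATION_ROUND_ATOL if round_mutations else 0):
                    raise GenealogyError(
                        f"non-integer mutation count {length} above {label!r}"
                    )
                node.mutations = int(r)
            else:
                node.time = float(length)
                node.mutations = 0
        node.children = [convert(c, False) for c in dnode.child_nodes()]
        return node

    return Genealogy(convert(dtree.seed_node, True))


def _format_length(node: Node, dialect: str) -> str:
    if dialect == "mutations":
        return str(node.mutations)
    return repr(float(node.time))


def write_tree(g: Genealogy, dialect: str) -> str:
    """Serialise to newick in the requested dialect.

    ``read_tree(write_tree(g, d), d)`` reproduces ``g`` up to child
    ordering.  Requesting a dialect whose annotation the tree does not
    carry is an error.
    """
    if dialect not in ("mutations", "times"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "mutations" and not g.has_mutations:
        raise GenealogyError("tree carries no mutation counts")
    if dialect == "times" and not g.has_times:
        raise GenealogyError("tree carries no time lengths")

    def render(node: Node, is_root: bool) -> str:
        if node.is_leaf:
            body = node.label
        else:
            inner = ",".join(render(c, False) for c in node.children)
            body = f"({inner})" + (node.label or "")
        if is_root:
            return body
        return f"{body}:{_format_length(node, dialect)}"

    return render(g.root, True) + ";"


# ---------------------------------------------------------------------------
# structural queries
# ---------------------------------------------------------------------------


def _leaf_depths(g: Genealogy, attr: str) -> dict[str, float]:
    """Per-leaf sum of the ``attr`` edge annotation along the root path."""
    depths: dict[str, float] = {}
    stack = [(g.root, 0)]
    while stack:
        node, acc = stack.pop()
        if node is not g.root:
            acc = acc + getattr(node, attr)
        if node.is_leaf:
            depths[node.label] = acc
        else:
            stack.extend((c, acc) for c in node.children)
    return depths


def leaf_path_counts(g: Genealogy) -> dict[str, int]:
    """L_i: total mutations on the root-to-leaf path, per leaf label."""
    if not g.has_mutations:
        if g.root.is_leaf:  # single-node tree: empty path
            return {g.root.label: 0}
        raise GenealogyError("tree carries no mutation counts")
    return _leaf_depths(g, "mutations")


def edge_leaf_counts(g: Genealogy) -> dict[Node, int]:
    """n_j: number of leaves below each edge, keyed by the child node."""
    counts: dict[int, int] = {}
    result: dict[Node, int] = {}
    for node in g.postorder():
        c = 1 if node.is_leaf else sum(counts[id(ch)] for ch in node.children)
        counts[id(node)] = c
        if node is not g.root:
            result[node] = c
    return result


def tmrca_from_times(g: Genealogy) -> float:
    """The common root-to-leaf time sum T (generations) of a timed tree."""
    if not g.has_times:
        raise GenealogyError("tree carries no time lengths")
    return g._check_ultrametric()


def haplotype_partition(g: Genealogy) -> HaplotypePartition:
    """Group leaves into identical-haplotype blocks under infinite sites.

    Two leaves carry the same haplotype iff every edge in the symmetric
    difference of their root paths bears zero mutations — equivalently,
    iff the sets of *mutated* edges on their root paths coincide (each
    mutation is a unique, identifiable event).  Each block records its
    multiplicity ``f_h`` and the shared mutation distance from the root
    ``l_h``.
    """
    if not g.has_mutations and not g.root.is_leaf:
        raise GenealogyError("tree carries no mutation counts")
    groups: dict[tuple[int, ...], list[str]] = {}
    dists: dict[tuple[int, ...], int] = {}
    stack: list[tuple[Node, tuple[int, ...], int]] = [(g.root, (), 0)]
    while stack:
        node, sig, depth = stack.pop()
        if node is not g.root and node.mutations:
            sig = sig + (id(node),)
            depth += node.mutations
        if node.is_leaf:
            groups.setdefault(sig, []).append(node.label)
            dists[sig] = depth
        else:
            stack.extend((c, sig, depth) for c in node.children)
    blocks = [
        HaplotypeBlock(frozenset(labels), len(labels), dists[sig])
        for sig, labels in groups.items()
    ]
    blocks.sort(key=lambda b: (b.root_distance, min(b.labels)))
    return HaplotypePartition(blocks)
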