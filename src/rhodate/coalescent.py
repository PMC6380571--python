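"""Constant-size Kingman coalescent simulation with infinite-sites mutations.

The simulator follows the haploid convention throughout: while ``k``
lineages remain, the waiting time to the next coalescence is
Exponential with rate ``k(k-1)/(2N)`` per generation in a haploid
population of constant size ``N``, and a uniformly random pair of
lineages merges.  The scaled mutation parameter is ``theta = 2*N*mu``
with ``mu`` the total per-lineage per-generation mutation rate of the
sequence.

Mutations are dropped on the genealogy under the infinite-sites model:
edge counts are independent Poisson, ``R_j ~ Po(mu * T_j)``, and each
mutation is a unique identifiable event, so the edge counts fully
determine the leaf haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genealogy import Genealogy, GenealogyError, Node, write_tree

__all__ = [
    "CoalescentConfig",
    "SimulationRecord",
    "FixtureSet",
    "whole_sequence_rate",
    "theta_from_mu",
    "mu_from_theta",
    "simulate_genealogy",
    "drop_mutations",
    "export_fixture",
]


def whole_sequence_rate(
    rate_per_site_per_year: float,
    generation_time_years: float,
    seq_length: int,
) -> float:
    """Total per-lineage per-generation mutation rate of a sequence.

    E.g. a 1.8e-7 per-bp per-year rate, 26-year generations and 500 bp
    give mu = 0.00234 per generation.
    """
    return rate_per_site_per_year * generation_time_years * seq_length


def theta_from_mu(N: float, mu: float) -> float:
    """theta = 2*N*mu (haploid convention)."""
    return 2.0 * N * mu


def mu_from_theta(N: float, theta: float) -> float:
    return theta / (2.0 * N)


@dataclass
class CoalescentConfig:
    """Parameters of one simulation study condition.

    Defaults are the constant-size study condition: haploid population
    size N = 1000, haploid sample size n = 100, whole-sequence mutation
    rate mu = 0.00234 per generation (theta = 4.68), 10,000 replicates.
    """

    n: int = 100
    N: float = 1000.0
    mu: float = 0.00234
    seed: int = 0
    reps: int = 10_000

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"sample size n must be >= 2, got {self.n}")
        if not self.N > 0:
            raise ValueError(f"population size N must be positive, got {self.N}")
        if self.mu < 0:
            raise ValueError(f"mutation rate mu must be >= 0, got {self.mu}")
        if self.reps < 1:
            raise ValueError(f"reps must be >= 1, got {self.reps}")

    @property
    def theta(self) -> float:
        return theta_from_mu(self.N, self.mu)

    @classmethod
    def from_theta(cls, theta: float, **kwargs) -> "CoalescentConfig":
        N = kwargs.pop("N", 1000.0)
        return cls(N=N, mu=mu_from_theta(N, theta), **kwargs)

    def replicate_rng(self, rep: int) -> np.random.Generator:
        """Independent substream for one replicate, order-independent."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(rep,))
        )


@dataclass
class SimulationRecord:
    """One replicate: true TMRCA, rho, age estimate and CI hits."""

    rep: int
    t_true: float
    rho: float
    t_hat: float
    ese: dict[str, float] = field(default_factory=dict)
    ci_low: dict[str, float] = field(default_factory=dict)
    ci_high: dict[str, float] = field(default_factory=dict)
    hit: dict[str, bool] = field(default_factory=dict)


def simulate_genealogy(n: int, N: float, rng: np.random.Generator) -> Genealogy:
    """One Kingman coalescent genealogy for ``n`` haploid samples.

    Returns an ultrametric timed Genealogy with binary internal nodes
    and leaves labelled ``t1..tn``.  E[TMRCA] = 2N(1 - 1/n) generations.
    """
    if n < 2:
        raise ValueError(f"need at least 2 lineages, got {n}")
    if not N > 0:
        raise ValueError(f"population size N must be positive, got {N}")
    active: list[Node] = [Node(label=f"t{i + 1}") for i in range(n)]
    ages = [0.0] * n
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 * N / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        left, right = active[i], active[j]
        left.time = t - ages[i]
        right.time = t - ages[j]
        parent = Node(children=[left, right])
        active[i] = parent
        ages[i] = t
        del active[j], ages[j]
    return Genealogy(active[0])


def drop_mutations(g: Genealogy, mu: float, rng: np.random.Generator) -> Genealogy:
    """Assign R_j ~ Po(mu*T_j) independently per edge, in place.

    The genealogy must carry times; its mutation counts are overwritten
    and the same object is returned, so repeated calls redraw mutations
    on a fixed tree.
    """
    if not g.has_times:
        raise GenealogyError("tree carries no time lengths")
    if mu < 0:
        raise ValueError(f"mutation rate mu must be >= 0, got {mu}")
    edges = g.edges
    counts = rng.poisson([mu * e.time for e in edges])
    for e, r in zip(edges, counts):
        e.mutations = int(r)
    g._has_mutations = True
    return g


_BASES = np.array(list("ACGT"))


@dataclass
class FixtureSet:
    """A simulated dataset realised as plain-text files."""

    fasta: str
    sequences: dict[str, str]
    newick_mutations: str
    newick_times: str | None


def export_fixture(g: Genealogy, seq_len: int, rng: np.random.Generator) -> FixtureSet:
    """Realise the mutations as sites of a sequence alignment.

    Each mutation gets a distinct site (drawn without replacement from
    ``1..seq_len``) and a derived allele differing from the root's base,
    so leaf sequences differ from the ancestral sequence at exactly the
    sites of their root-path mutations.  The FASTA includes the
    ancestral sequence under the label ``"MRCA"``; newick text is
    produced in the mutations dialect and, when times are present, the
    times dialect.
    """
    if not g.has_mutations:
        raise GenealogyError("tree carries no mutation counts")
    edges = g.edges
    total = sum(e.mutations for e in edges)
    if total > seq_len:
        raise ValueError(
            f"{total} mutations cannot fit {seq_len} sites under infinite sites"
        )
    root_seq = rng.choice(_BASES, size=seq_len)
    sites = rng.choice(seq_len, size=total, replace=False)
    # derived allele: shift the ancestral base by 1..3 in ACGT order
    shifts = rng.integers(1, 4, size=total)
    pos = 0
    edge_events: dict[int, list[tuple[int, str]]] = {}
    for e in edges:
        events = []
        for _ in range(e.mutations):
            s = int(sites[pos])
            base_idx = int(np.where(_BASES == root_seq[s])[0][0])
            derived = _BASES[(base_idx + int(shifts[pos])) % 4]
            events.append((s, str(derived)))
            pos += 1
        edge_events[id(e)] = events

    sequences: dict[str, str] = {"MRCA": "".join(root_seq)}
    stack: list[tuple[Node, tuple[tuple[int, str], ...]]] = [(g.root, ())]
    while stack:
        node, acc = stack.pop()
        if node is not g.root:
            acc = acc + tuple(edge_events[id(node)])
        if node.is_leaf:
            seq = list(root_seq)
            for s, derived in acc:
                seq[s] = derived
            sequences[node.label] = "".join(seq)
        else:
            stack.extend((c, acc) for c in node.children)

    # leaf order follows the tree; MRCA first
    order = ["MRCA"] + [lf.label for lf in g.leaves]
    fasta = "".join(f">{name}\n{sequences[name]}\n" for name in order)
    return FixtureSet(
        fasta=fasta,
        sequences=sequences,
        newick_mutations=write_tree(g, "mutations"),
        newick_times=write_tree(g, "times") if g.has_times else None,
    )
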