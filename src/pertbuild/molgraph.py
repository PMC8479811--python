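"""Bond graph and ring perception.

Rings are perceived as a smallest-set-of-smallest-rings (SSSR): simple
cycles are enumerated up to a size cap, sorted by (length, lowest atom
indices), and picked greedily while they are linearly independent in the
GF(2) edge space, until the cyclomatic number is reached.  Ring pairs are
classified as fused (exactly one shared edge), spiro (exactly one shared
atom), bridged (two or more shared atoms that are not a single shared
edge) or disjoint — the classes the matching policies distinguish.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .core import ForceFieldTopology, TopologyError

#: Cycles larger than this are treated as acyclic by the matching policies
#: (macrocycles are outside the demonstrated scope of the builder).
DEFAULT_RING_CAP = 12


@dataclass
class MolGraph:
    """Undirected bond graph of one topology."""

    graph: nx.Graph

    @property
    def nodes(self) -> set[int]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[int]]:
        return {frozenset(e) for e in self.graph.edges}

    def neighbors(self, i: int) -> set[int]:
        return set(self.graph.neighbors(i))

    def has_edge(self, i: int, j: int) -> bool:
        return self.graph.has_edge(i, j)


@dataclass
class RingSystem:
    rings: list[tuple[int, ...]]  # each a closed cycle, canonical rotation
    ring_pair_relation: dict[tuple[int, int], str] = field(default_factory=dict)
    ring_membership: dict[int, set[int]] = field(default_factory=dict)

    def ring_atoms(self) -> set[int]:
        return set(self.ring_membership)

    def is_ring_atom(self, i: int) -> bool:
        return i in self.ring_membership

    def relation(self, a: int, b: int) -> str:
        return self.ring_pair_relation.get((min(a, b), max(a, b)), "disjoint")

    def bridged_partners(self, r: int) -> set[int]:
        return {
            b if a == r else a
            for (a, b), rel in self.ring_pair_relation.items()
            if rel == "bridged" and r in (a, b)
        }


def build_graph(top: ForceFieldTopology) -> MolGraph:
    """Bond graph of a topology; nodes = atoms, edges = bonds."""
    if len(top.atoms) == 0:
        raise TopologyError("cannot build a graph for an empty topology")
    g = nx.Graph()
    g.add_nodes_from(range(len(top.atoms)))
    g.add_edges_from((i, j) for i, j, _ in top.bonds)
    return MolGraph(g)


def _canonical_cycle(cycle: list[int]) -> tuple[int, ...]:
    """Rotate/reflect a cycle so it starts at its smallest atom and runs
    toward its smaller neighbor — a unique representative per ring."""
    n = len(cycle)
    k = cycle.index(min(cycle))
    rot = cycle[k:] + cycle[:k]
    fwd = tuple(rot)
    rev = tuple([rot[0]] + rot[1:][::-1])
    return min(fwd, rev)


def _cycle_edges(cycle: tuple[int, ...]) -> set[frozenset[int]]:
    return {frozenset((cycle[i], cycle[(i + 1) % len(cycle)])) for i in range(len(cycle))}


def perceive_rings(graph: MolGraph, cap: int = DEFAULT_RING_CAP) -> RingSystem:
    """Deterministic SSSR with pairwise fused/bridged/spiro classification."""
    g = graph.graph
    n_independent = g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)
    if n_independent <= 0:
        return RingSystem(rings=[])

    cycles = [
        _canonical_cycle(list(c))
        for c in nx.simple_cycles(g, length_bound=cap)
        if len(c) >= 3
    ]
    cycles = sorted(set(cycles), key=lambda c: (len(c), c))

    edge_index = {frozenset(e): k for k, e in enumerate(g.edges)}
    basis_rows: list[int] = []  # GF(2) row-echelon bitmasks
    chosen: list[tuple[int, ...]] = []
    for cyc in cycles:
        vec = 0
        for e in _cycle_edges(cyc):
            vec ^= 1 << edge_index[e]
        v = vec
        for row in basis_rows:
            v = min(v, v ^ row)
        if v:  # independent of everything chosen so far
            chosen.append(cyc)
            basis_rows.append(vec)
            basis_rows.sort(reverse=True)
            # re-reduce to keep reduction canonical
            reduced: list[int] = []
            for row in basis_rows:
                r = row
                for q in reduced:
                    r = min(r, r ^ q)
                if r:
                    reduced.append(r)
                    reduced.sort(reverse=True)
            basis_rows = reduced
        if len(chosen) == n_independent:
            break

    rs = RingSystem(rings=chosen)
    for rid, cyc in enumerate(chosen):
        for a in cyc:
            rs.ring_membership.setdefault(a, set()).add(rid)
    for (i, ci), (j, cj) in combinations(enumerate(chosen), 2):
        shared_atoms = set(ci) & set(cj)
        if not shared_atoms:
            rel = "disjoint"
        else:
            shared_edges = _cycle_edges(ci) & _cycle_edges(cj)
            if len(shared_atoms) == 1:
                rel = "spiro"
            elif len(shared_atoms) == 2 and len(shared_edges) == 1:
                rel = "fused"
            else:
                rel = "bridged"
        if rel != "disjoint":
            rs.ring_pair_relation[(i, j)] = rel
    return rs


def first_neighbors(graph: MolGraph, atoms: set[int]) -> set[int]:
    """Union of neighbors of ``atoms`` minus ``atoms`` itself."""
    unknown = set(atoms) - graph.nodes
    if unknown:
        raise TopologyError(f"unknown atom indices {sorted(unknown)}")
    out: set[int] = set()
    for a in atoms:
        out |= graph.neighbors(a)
    return out - set(atoms)
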