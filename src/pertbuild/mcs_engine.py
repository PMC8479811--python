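"""Iterative VF-style maximum-common-substructure search with pruning.

The search enumerates multistate atom mappings by depth-first branching on
one pivot atom at a time: the smallest unassigned atom adjacent to the
matched region (or the smallest unassigned atom overall while no two-state
match exists yet).  Branches assign the pivot either to a match tuple built
from compatible unassigned atoms of the other states or explicitly to a
dummy.  Because the pivot is a deterministic function of the partial
assignment, every complete assignment is enumerated exactly once.

Bond preservation (a bond between two matched atoms must exist in every
state in which both match entries are real — the search may never create or
remove bonds) is enforced on every candidate.  Ring-to-nonring match
budgets are enforced incrementally; the full ring policy is validated when
a solution completes.  Branches whose admissible lower bound exceeds the
best enumerated score are pruned.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

from .core import DUMMY, ForceFieldTopology, TopologyError, atoms_equivalent
from .molgraph import MolGraph, RingSystem, build_graph, perceive_rings
from .options import ScoreSpec, SearchOptions
from .scoring import INFEASIBLE, evaluate_solution, lower_bound_key
from .solution import AtomMatch, MatchSolution, classify_solution

log = logging.getLogger(__name__)


class SearchBudgetExceeded(RuntimeError):
    """The configured node-expansion budget was exhausted (the MCS problem
    is of exponential complexity; raise the budget or simplify the input)."""


def initial_pairs(states: list[ForceFieldTopology]) -> list[AtomMatch]:
    """The seed candidate list: for two states of sizes n and m, all n x m
    atom pairs; for N states, every cross-state seed tuple anchored on
    state 0."""
    if len(states) < 2:
        raise TopologyError("at least two states are required")
    n = len(states)
    out: list[AtomMatch] = []
    if n == 2:
        for i in range(len(states[0])):
            for j in range(len(states[1])):
                out.append(AtomMatch((i, j)))
        return out
    for i in range(len(states[0])):
        others = [[DUMMY] + list(range(len(states[s]))) for s in range(1, n)]
        for combo in itertools.product(*others):
            if all(e is DUMMY for e in combo):
                continue
            out.append(AtomMatch((i, *combo)))
    return out


# ---------------------------------------------------------------------------
# ring policy


def enforce_ring_policy(sol: MatchSolution, rings: list[RingSystem],
                        opts: SearchOptions,
                        graphs: list[MolGraph] | None = None) -> bool:
    """True if the solution's ring-atom matches obey the configured
    policies (checked for every ordered state pair).

    complete_individual_rings: within a polycyclic system each individual
    ring is either fully matched or effectively unmatched; matched ring
    atoms not covered by any completely matched ring fall under the partial
    budget of ``ring_nonring_policy`` (at most two atoms sharing a bond /
    one atom / none) — the same budget that governs ring-to-nonring
    matches and ring-ring pairs without a complete correspondence.
    complete_only: a connected ring system (rings related by fusion or
    bridging; spiro rings count as separate systems) is matched in its
    entirety or carries no ring-to-ring match at all.  Rings in a bridged
    relation are all-or-nothing as a pair under either policy.
    """
    graphs = graphs or [build_graph(t) for t in sol.states]
    budget = opts.ring_partial_budget
    n = sol.n_states
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            mapping = {m[s]: m[t] for m in sol.matches
                       if m[s] is not DUMMY and m[t] is not DUMMY}
            rs, rt = rings[s], rings[t]
            complete = [set(r) <= mapping.keys() for r in rs.rings]
            covered: set[int] = set()
            for rid, comp in enumerate(complete):
                if comp:
                    covered |= set(rs.rings[rid])
            if opts.ring_policy == "complete_only":
                for system in _ring_systems(rs):
                    atoms = set().union(*(rs.rings[r] for r in system))
                    rr = [a for a in atoms
                          if a in mapping and rt.is_ring_atom(mapping[a])]
                    if not rr or all(complete[r] for r in system):
                        continue
                    if len(system) >= 2:
                        return False  # polycyclic system matched in part
                    # a lone ring may share its spiro junction with a
                    # completely matched sibling ring
                    if any(a not in covered for a in rr):
                        return False
            for rid, ring in enumerate(rs.rings):
                matched = [a for a in ring if a in mapping]
                # bridged pairs: only a complete match of both rings
                for other in rs.bridged_partners(rid):
                    pair_atoms = set(ring) | set(rs.rings[other])
                    if any(a in mapping for a in pair_atoms):
                        if not (complete[rid] and complete[other]):
                            return False
                uncovered = [a for a in matched if a not in covered]
                if opts.ring_policy == "complete_only":
                    uncovered = [a for a in uncovered
                                 if not rt.is_ring_atom(mapping[a])]
                if len(uncovered) > budget:
                    return False
                if len(uncovered) == 2 and not graphs[s].has_edge(*uncovered):
                    return False
    return True


def _ring_systems(rs: RingSystem) -> list[list[int]]:
    """Connected components of rings under fused/bridged relations."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(rs.rings)))
    for (a, b), rel in rs.ring_pair_relation.items():
        if rel in ("fused", "bridged"):
            g.add_edge(a, b)
    return [sorted(c) for c in nx.connected_components(g)]


def _ring_nonring_candidate_ok(entries: tuple, sol_matches: list[AtomMatch],
                               rings: list[RingSystem],
                               graphs: list[MolGraph],
                               opts: SearchOptions) -> bool:
    """Incremental ring-to-nonring budget: these matches can never later be
    covered by a complete ring match, so the budget may be enforced as soon
    as a candidate introduces one."""
    budget = opts.ring_partial_budget
    states = [s for s, e in enumerate(entries) if e is not DUMMY]
    for s in states:
        for t in states:
            if s == t:
                continue
            if not rings[s].is_ring_atom(entries[s]):
                continue
            if rings[t].is_ring_atom(entries[t]):
                continue
            if budget == 0:
                return False
            for rid in rings[s].ring_membership[entries[s]]:
                ring = rings[s].rings[rid]
                prior = [m[s] for m in sol_matches
                         if m[s] is not DUMMY and m[t] is not DUMMY
                         and m[s] in ring and not rings[t].is_ring_atom(m[t])]
                if len(prior) + 1 > budget:
                    return False
                if budget == 2 and len(prior) == 1 and \
                        not graphs[s].has_edge(entries[s], prior[0]):
                    return False
    return True


# ---------------------------------------------------------------------------
# public single-step operations


def add_match(sol: MatchSolution, match: AtomMatch) -> MatchSolution:
    """Append one atom match, revalidating all solution invariants and
    recomputing the perturbed-term record."""
    new = MatchSolution(sol.states, list(sol.matches) + [match], sol.options)
    rings = [perceive_rings(build_graph(t), sol.options.ring_size_cap)
             for t in sol.states]
    graphs = [build_graph(t) for t in sol.states]
    if not _ring_nonring_candidate_ok(match.entries, sol.matches, rings,
                                      graphs, sol.options):
        raise TopologyError("match violates the ring/nonring policy")
    return new


def expand_candidates(sol: MatchSolution, opts: SearchOptions | None = None,
                      spec: ScoreSpec | None = None) -> list[AtomMatch]:
    """Allowed extensions of a partial solution for the current pivot atom,
    sorted so the lowest-lower-bound extension comes first."""
    opts = opts or sol.options
    spec = spec or ScoreSpec()
    eng = _Engine(sol.states, opts, spec)
    cands = eng.candidates_for(list(sol.matches))
    return cands


def match_dihedrals(sol: MatchSolution, opts: SearchOptions | None = None) -> dict:
    """Classify every dihedral of the solution: 'matched' (parameters
    equal), 'perturbed', 'multiplicity' or 'created_removed'."""
    opts = opts or sol.options
    cls = classify_solution(sol.states, sol.matches, opts)
    report = {"matched": [], "perturbed": [], "multiplicity": [],
              "created_removed": []}
    flagged_keys = set()
    for pt in cls.perturbed_terms:
        if pt.kind != "dihedral":
            continue
        if pt.created_removed:
            report["created_removed"].append(pt)
        elif pt.category == "multiplicity":
            report["multiplicity"].append(pt)
        else:
            report["perturbed"].append(pt)
        flagged_keys.add(pt.match_ids)
    tup_of = [sol.match_of(s) for s in range(sol.n_states)]
    seen = set()
    for s, top in enumerate(sol.states):
        for i, j, k, l, _ in top.dihedrals:
            if any(x not in tup_of[s] for x in (i, j, k, l)):
                continue
            ids = tuple(tup_of[s][x] for x in (i, j, k, l))
            key = min(ids, ids[::-1])
            if key not in flagged_keys and key not in seen:
                seen.add(key)
                report["matched"].append(key)
    return report


# ---------------------------------------------------------------------------
# the search engine


@dataclass
class SearchResult:
    solutions: list[MatchSolution]
    nodes_expanded: int
    best_key: tuple


class _Engine:
    def __init__(self, states: list[ForceFieldTopology],
                 opts: SearchOptions, spec: ScoreSpec):
        if len(states) < 2:
            raise TopologyError("at least two states are required")
        for s, t in enumerate(states):
            if len(t) == 0:
                raise TopologyError(f"state {s} is empty")
            t.validate()
        self.states = states
        self.opts = opts
        self.spec = spec
        self.n = len(states)
        self.graphs = [build_graph(t) for t in states]
        self.rings = [perceive_rings(g, opts.ring_size_cap) for g in self.graphs]
        self.bonds = [t.bond_set() for t in states]
        keep = opts.enumerate_all_best
        self.keep_equal = (self.n == 2) if keep is None else keep
        self.best_key: tuple | None = None
        self.best: list[list[AtomMatch]] = []
        self.nodes = 0

    # -- bookkeeping --------------------------------------------------------
    def _assigned(self, matches: list[AtomMatch]) -> list[set[int]]:
        out = [set() for _ in range(self.n)]
        for m in matches:
            for s, e in enumerate(m.entries):
                if e is not DUMMY:
                    out[s].add(e)
        return out

    def _anchors(self, matches: list[AtomMatch]) -> list[set[int]]:
        out = [set() for _ in range(self.n)]
        for m in matches:
            rs = m.real_states
            if len(rs) >= 2:
                for s in rs:
                    out[s].add(m[s])
        return out

    def _pivot(self, matches: list[AtomMatch]):
        """(state, atom) to branch on next, or None at a leaf."""
        assigned = self._assigned(matches)
        anchors = self._anchors(matches)
        if any(anchors):
            frontier = []
            for s in range(self.n):
                for a in anchors[s]:
                    for j in self.graphs[s].neighbors(a):
                        if j not in assigned[s]:
                            frontier.append((s, j))
            return min(frontier) if frontier else None
        unassigned = [(s, i) for s in range(self.n)
                      for i in range(len(self.states[s])) if i not in assigned[s]]
        return min(unassigned) if unassigned else None

    def _compatible(self, matches: list[AtomMatch],
                    entries: tuple) -> bool:
        """Bond preservation of a candidate tuple against all prior matches.

        Against a matched (multi-real) tuple, a bond must exist in either
        every or none of the candidate's real states — a tuple absent from
        one of them counts as unbonded there, so partially overlapping
        scaffold tuples cannot be chained through a single shared state
        into a chimeric union atom.  Dummy-matched (single-real) tuples are
        one state's private branch and impose no constraint.
        """
        real = [(s, e) for s, e in enumerate(entries) if e is not DUMMY]
        for m in matches:
            if len(m.real_states) < 2:
                continue
            for (s, es), (t, et) in itertools.combinations(real, 2):
                bs = m[s] is not DUMMY and frozenset((es, m[s])) in self.bonds[s]
                bt = m[t] is not DUMMY and frozenset((et, m[t])) in self.bonds[t]
                if bs != bt:
                    return False
        return True

    def candidates_for(self, matches: list[AtomMatch],
                       exact_sort: bool = True) -> list[AtomMatch]:
        pivot = self._pivot(matches)
        if pivot is None:
            return []
        ps, pa = pivot
        assigned = self._assigned(matches)
        anchors = self._anchors(matches)
        seeded = any(anchors)

        per_state: list[list] = []
        for t in range(self.n):
            if t == ps:
                per_state.append([pa])
                continue
            opts_t: list = [DUMMY]
            pool = [j for j in range(len(self.states[t])) if j not in assigned[t]]
            if seeded:
                # atoms whose pairing with the pivot is bond-preserving
                pool = [j for j in pool
                        if self._compatible(matches, _sparse(self.n, {ps: pa, t: j}))]
            opts_t.extend(pool)
            per_state.append(opts_t)

        cands: list[AtomMatch] = []
        for combo in itertools.product(*per_state):
            entries = tuple(combo)
            if not self._compatible(matches, entries):
                continue
            if not _ring_nonring_candidate_ok(entries, matches, self.rings,
                                              self.graphs, self.opts):
                continue
            cands.append(AtomMatch(entries))

        def canon(cand: AtomMatch):
            return tuple(len(self.states[s]) if e is DUMMY else e
                         for s, e in enumerate(cand.entries))

        if exact_sort:
            def sort_key(cand: AtomMatch):
                child = MatchSolution.trusted(self.states, matches + [cand],
                                              self.opts)
                return (lower_bound_key(child, self.spec, self.graphs),
                        canon(cand))
        else:
            # cheap proxy for the lower bound: fewest new dummy entries,
            # then fewest atom-level mismatches, then canonical order
            def sort_key(cand: AtomMatch):
                real = [self.states[s].atoms[e]
                        for s, e in enumerate(cand.entries) if e is not DUMMY]
                mism = 0
                for a in real[1:]:
                    t, m_, q = atoms_equivalent(real[0], a)
                    mism += (not t) + (not m_) + (not q)
                return (cand.n_dummy, mism, canon(cand))

        cands.sort(key=sort_key)
        return cands

    # -- depth-first branch and bound ---------------------------------------
    def run(self) -> SearchResult:
        self._dfs([])
        sols = []
        for matches in self.best:
            sol = MatchSolution(self.states, matches, self.opts)
            sol.score = evaluate_solution(sol, self.spec)
            sols.append(sol)
        if not self.keep_equal:
            sols = sols[:1]
        return SearchResult(sols, self.nodes, self.best_key or ())

    def _dfs(self, matches: list[AtomMatch]) -> None:
        self.nodes += 1
        if self.nodes > self.opts.max_nodes:
            raise SearchBudgetExceeded(
                f"node-expansion budget of {self.opts.max_nodes} exhausted "
                f"after matching {len(matches)} tuples")
        pivot = self._pivot(matches)
        if pivot is None:
            self._record_leaf(matches)
            return
        partial = MatchSolution.trusted(self.states, matches, self.opts)
        if self.opts.prune and self.best_key is not None:
            lb = lower_bound_key(partial, self.spec, self.graphs)
            if lb > self.best_key or (lb == self.best_key and not self.keep_equal):
                return
        for cand in self.candidates_for(matches, exact_sort=False):
            self._dfs(matches + [cand])

    def _record_leaf(self, matches: list[AtomMatch]) -> None:
        sol = MatchSolution.trusted(self.states, matches, self.opts).completed()
        cls = sol.classify()
        from .scoring import _key_from_counts  # sibling-internal
        key = _key_from_counts(cls.counts, self.spec, cls.feasible)
        if key[0] == INFEASIBLE:
            return
        if not enforce_ring_policy(sol, self.rings, self.opts, self.graphs):
            return
        if self.best_key is None or key < self.best_key:
            self.best_key = key
            self.best = [sol.matches]
        elif key == self.best_key and self.keep_equal and \
                len(self.best) < self.opts.max_solutions:
            if sol.matches not in self.best:
                self.best.append(sol.matches)


def _sparse(n: int, entries: dict[int, int]) -> tuple:
    out = [DUMMY] * n
    for s, e in entries.items():
        out[s] = e
    return tuple(out)


def search(states: list[ForceFieldTopology],
           opts: SearchOptions | None = None,
           spec: ScoreSpec | None = None) -> list[MatchSolution]:
    """All best-scoring complete solutions (up to ``max_solutions``).

    Complete means every real atom of every state is present, matched
    either to real atoms or explicitly to a dummy.  Output order is
    deterministic; pruning never removes an optimal solution.
    """
    opts = opts or SearchOptions()
    spec = spec or ScoreSpec()
    eng = _Engine(states, opts, spec)
    result = eng.run()
    log.info("MCS search over %d states: %d node(s), best key %s, %d solution(s)",
             len(states), result.nodes_expanded, result.best_key,
             len(result.solutions))
    for sol in result.solutions:
        log.debug("score breakdown: %s", dict(sol.score.breakdown))
    return result.solutions
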