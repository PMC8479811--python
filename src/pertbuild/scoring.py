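"""Penalty scoring of match solutions, pruning bound, RMSD tie-breakers.

The score of a solution is the weighted sum of its penalty-category counts
(dummy matches dominate by default, so the search primarily maximizes the
number of matched atoms).  The lower bound used for branch-and-bound
pruning is admissible: the already accumulated penalty plus the dummy
penalty of every atom that can no longer be matched (atoms disconnected
from the growth frontier, plus — for two states — the unavoidable size
imbalance of what remains).

Coordinate-based ranking breaks score ties: for a pair of states the
atom-positional RMSD over matched atoms, computed *without* least-squares
fitting (the input poses carry the information, e.g. ligands posed in a
binding pocket); for N states either the root-mean-square of all pairwise
RMSDs, <RMSD^2>^1/2, or the root-mean-square fluctuation <RMSF^2>^1/2.
The two multistate forms are related by <RMSD^2> = 2N/(N-1) <RMSF^2>.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .core import DUMMY, CoordinateSet, TopologyError
from .molgraph import build_graph
from .options import CATEGORIES, ScoreSpec
from .solution import MatchSolution

INFEASIBLE = math.inf


@dataclass
class ScoreValue:
    total: float
    breakdown: Counter = field(default_factory=Counter)
    lower_bound: float = 0.0
    key: tuple = ()  # comparable; lexicographic (dummies, mismatch) by default

    def __repr__(self) -> str:
        parts = ", ".join(f"{c}={n}" for c, n in sorted(self.breakdown.items()) if n)
        return f"ScoreValue(total={self.total}, {parts or 'clean'})"


def _key_from_counts(counts: Counter, spec: ScoreSpec, feasible: bool) -> tuple:
    if not feasible or any(counts.get(c, 0) for c in spec.forbid):
        return (INFEASIBLE, INFEASIBLE)
    if spec.custom_score is not None:
        return (0.0, float(spec.custom_score(dict(counts))))
    mismatch = sum(counts.get(c, 0) * spec.weight(c)
                   for c in CATEGORIES if c != "dummy")
    if spec.lexicographic:
        return (float(counts.get("dummy", 0)), mismatch)
    return (0.0, counts.get("dummy", 0) * spec.w_dummy + mismatch)


def _total_from_key(key: tuple, spec: ScoreSpec) -> float:
    if key[0] == INFEASIBLE:
        return INFEASIBLE
    if spec.custom_score is not None or not spec.lexicographic:
        return key[1]
    return key[0] * spec.w_dummy + key[1]


def evaluate_solution(sol: MatchSolution, spec: ScoreSpec) -> ScoreValue:
    """Score = sum over categories of count x weight; forbidden categories
    with a nonzero count (or an infeasible term pattern) give the infinite
    sentinel."""
    cls = sol.classify()
    key = _key_from_counts(cls.counts, spec, cls.feasible)
    total = _total_from_key(key, spec)
    sv = ScoreValue(total=total, breakdown=cls.counts, key=key)
    sv.lower_bound = total if sol.is_complete else lower_bound(sol, spec)
    return sv


def lower_bound_key(sol: MatchSolution, spec: ScoreSpec,
                    graphs=None) -> tuple:
    """Admissible comparison key: no completion of ``sol`` scores below it."""
    cls = sol.classify()
    key = _key_from_counts(cls.counts, spec, cls.feasible)
    if key[0] == INFEASIBLE:
        return key
    forced = _forced_dummies(sol, graphs)
    if spec.custom_score is not None:
        return key  # no structural bound for arbitrary user scores
    if spec.lexicographic:
        return (key[0] + forced, key[1])
    return (0.0, key[1] + forced * spec.w_dummy)


def lower_bound(sol: MatchSolution, spec: ScoreSpec) -> float:
    """Scalar form of the admissible bound (equals the total on complete
    solutions)."""
    return _total_from_key(lower_bound_key(sol, spec), spec)


def _forced_dummies(sol: MatchSolution, graphs=None) -> int:
    """Dummy entries every completion must at least add beyond the current
    count.

    Every atom sits in exactly one match tuple of a complete solution, so
    the total number of dummy entries obeys the identity
    ``D = N * T - sum_s n_s`` with ``T`` the number of tuples.  ``T`` is
    bounded below by the current tuple count plus one tuple per atom that
    is unreachable from the matched region (connected growth forces those
    into dummy singletons) plus, among the reachable remainder, the largest
    per-state atom count (atoms of one state never share a tuple).
    """
    n = sol.n_states
    anchors = [set() for _ in range(n)]
    current_dummies = 0
    for m in sol.matches:
        current_dummies += m.n_dummy
        if len(m.real_states) >= 2:
            for s in m.real_states:
                anchors[s].add(m[s])
    has_real = any(anchors)
    graphs = graphs or [build_graph(t) for t in sol.states]
    n_unreachable = 0
    max_reachable = 0
    for s in range(n):
        unassigned = set(range(len(sol.states[s]))) - sol.assigned(s)
        if not has_real:
            max_reachable = max(max_reachable, len(unassigned))
            continue
        seen: set[int] = set()
        stack = [j for a in anchors[s] for j in graphs[s].neighbors(a)
                 if j in unassigned]
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            stack.extend(j for j in graphs[s].neighbors(x)
                         if j in unassigned and j not in seen)
        n_unreachable += len(unassigned) - len(seen)
        max_reachable = max(max_reachable, len(seen))
    t_min = len(sol.matches) + n_unreachable + max_reachable
    d_min = n * t_min - sum(len(t) for t in sol.states)
    return max(0, d_min - current_dummies)


# ---------------------------------------------------------------------------
# coordinate-based ranking


def _full_real_tuples(sol: MatchSolution) -> list:
    return [m for m in sol.matches if len(m.real_states) == sol.n_states]


def rmsd_of_mapping(sol: MatchSolution, coords: list[CoordinateSet],
                    mode: str = "rmsd") -> float:
    """Positional spread of the mapping, in nm, without superposition.

    Two states: plain RMSD over matched atom pairs.  N states: over match
    tuples that are real in every state, either the root-mean-square of the
    pairwise RMSDs (``mode="rmsd"``) or the root-mean-square fluctuation
    about the tuple centroids (``mode="rmsf"``).
    """
    if len(coords) != sol.n_states:
        raise TopologyError("one coordinate set per state is required")
    for c, t in zip(coords, sol.states):
        c.validate_against(t)
    if mode not in ("rmsd", "rmsf"):
        raise TopologyError(f"unknown rmsd mode {mode!r}")

    tuples = _full_real_tuples(sol)
    if not tuples:
        raise TopologyError("no match tuple is real in every state "
                            "(at least one real-real match is required)")
    # (n_tuples, n_states, 3)
    x = np.array([[coords[s].positions[m[s]] for s in range(sol.n_states)]
                  for m in tuples])
    if mode == "rmsf":
        dev = x - x.mean(axis=1, keepdims=True)
        return float(np.sqrt((dev ** 2).sum(axis=2).mean()))
    n = sol.n_states
    sq = []
    for s in range(n):
        for t in range(s + 1, n):
            d = x[:, s, :] - x[:, t, :]
            sq.append((d ** 2).sum(axis=1).mean())
    return float(np.sqrt(np.mean(sq)))


def select_best(solutions: list[MatchSolution],
                coords: list[CoordinateSet] | None = None,
                spec: ScoreSpec | None = None,
                mode: str = "rmsd") -> MatchSolution:
    """Minimal-score solution; score ties broken by minimal mapping RMSD
    when coordinates are given, else by a deterministic canonical order."""
    if not solutions:
        raise TopologyError("select_best requires a non-empty solution list")
    spec = spec or ScoreSpec()

    def canon(sol: MatchSolution) -> tuple:
        return tuple(sorted(
            tuple(-1 if e is DUMMY else e for e in m.entries) for m in sol.matches))

    def sort_key(sol: MatchSolution):
        sv = sol.score if sol.score is not None else evaluate_solution(sol, spec)
        rmsd = rmsd_of_mapping(sol, coords, mode=mode) if coords is not None else 0.0
        return (sv.key, rmsd, canon(sol))

    return min(solutions, key=sort_key)
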