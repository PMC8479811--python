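"""Simultaneous MCS over three or more topologies; EDS topologies; cycles.

The multistate search finds the minimum structure of which every input
compound is a substructure — a common scaffold.  Its default scoring
forbids any perturbation of bonded interactions (only atom types, masses,
charges and dummy designations may switch between states), which is the
setting used to build enveloping-distribution-sampling (EDS) reference
topologies.  The same multistate mapping also yields a consistent set of
pairwise perturbation topologies forming a closed thermodynamic cycle.

Multistate runs take distinctly longer than pairwise ones (the joint
search space grows with every added state); large, diverse compound sets
are out of scope and hit the node-expansion budget instead of running
forever.
"""

from __future__ import annotations

import itertools
import logging

from .core import ForceFieldTopology, TopologyError
from .mcs_engine import search
from .options import ScoreSpec, SearchOptions, eds_score_spec
from .pert_builder import (EDSTopology, PerturbationTopology,
                           build_pert_topology, _build_union, _project)
from .solution import MatchSolution

log = logging.getLogger(__name__)


class NoFeasibleSolution(TopologyError):
    """No complete mapping satisfies the forbid constraints/policies."""


def multistate_search(states: list[ForceFieldTopology],
                      opts: SearchOptions | None = None,
                      spec: ScoreSpec | None = None) -> MatchSolution:
    """Single best solution over all states (N >= 2).

    With the default (EDS-oriented) score spec, any solution implying a
    bonded-term perturbation is rejected outright.
    """
    if len(states) < 2:
        raise TopologyError("multistate search requires at least two states")
    opts = opts or SearchOptions()
    spec = spec if spec is not None else eds_score_spec()
    sols = search(states, opts, spec)
    if not sols:
        raise NoFeasibleSolution(
            "no complete mapping satisfies the matching constraints")
    return sols[0]


def build_eds_topology(sol: MatchSolution) -> EDSTopology:
    """Union (reference-state) topology representing every state of a
    complete multistate solution; bonded perturbations are a hard error."""
    if not sol.is_complete:
        raise TopologyError("the match solution is not complete")
    cls = sol.classify()
    for pt in cls.perturbed_terms:
        if pt.kind in ("bond", "angle", "dihedral", "improper"):
            raise TopologyError(
                f"solution perturbs {pt.kind} term {pt.match_ids}: "
                "an EDS topology requires identical bonded terms in all states")
    state_ids = list(range(sol.n_states))
    rows = _project(sol, state_ids)
    eds = _build_union(sol, state_ids, rows, EDSTopology)
    eds.validate()
    return eds


def pairwise_from_multistate(sol: MatchSolution) -> list[PerturbationTopology]:
    """All N(N-1)/2 pairwise perturbation topologies of one multistate
    mapping — a closed thermodynamic cycle by construction."""
    if sol.n_states < 3:
        raise TopologyError(
            "pairwise extraction needs three or more states; run the "
            "pairwise search directly for two")
    if not sol.is_complete:
        raise TopologyError("the match solution is not complete")
    out = []
    for a, b in itertools.combinations(range(sol.n_states), 2):
        out.append(build_pert_topology(sol, a, b))
    log.info("extracted %d pairwise perturbation topologies", len(out))
    return out
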