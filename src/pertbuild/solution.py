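"""Atom-match solutions and perturbed-term classification.

A :class:`MatchSolution` is an ordered list of :class:`AtomMatch` tuples —
one entry per state, each a real atom index or the DUMMY marker.  Classifying
a (partial or complete) solution walks every bonded term whose atoms are all
assigned and compares parameters across the states in which all participating
match tuples are real; terms touching a dummy-matched atom belong to the
dummy region of one state and are never counted as perturbations.

Dihedral angles are paired by one of two procedures: ``all_four_atoms``
(a dihedral matches only if all four mapped atoms carry a dihedral in the
other state too; a multiplicity difference then needs the explicit
multiplicity-change permission) or ``middle_two_atoms`` (dihedrals sharing
the mapped central bond are paired up; parameter differences, multiplicity
included, count as ordinary perturbations).  Creation/removal of angles,
dihedrals and impropers is permitted only with ``allow_make_break_bonded``;
bonds can never be created or removed by a match.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import (DUMMY, ANGLE, BOND, DIHEDRAL, IMPROPER, Atom,
                   ForceFieldTopology, TopologyError, atoms_equivalent,
                   params_equal)
from .options import ScoreSpec, SearchOptions


@dataclass(frozen=True)
class AtomMatch:
    """One match tuple: per-state real atom index or DUMMY (None)."""

    entries: tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        if all(e is DUMMY for e in self.entries):
            raise TopologyError("an atom match must contain at least one real atom")

    def __getitem__(self, s: int) -> Optional[int]:
        return self.entries[s]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_dummy(self) -> int:
        return sum(1 for e in self.entries if e is DUMMY)

    @property
    def real_states(self) -> tuple[int, ...]:
        return tuple(s for s, e in enumerate(self.entries) if e is not DUMMY)


@dataclass
class PerturbedTerm:
    """One term-level mismatch record."""

    category: str            # atomtype/mass/charge/bond/angle/dihedral/improper/multiplicity
    kind: str                # atom or bond/angle/dihedral/improper
    match_ids: tuple[int, ...]
    per_state: dict[int, object]   # state -> resolved params (or None if absent)
    created_removed: bool = False


@dataclass
class Classification:
    counts: Counter
    perturbed_terms: list[PerturbedTerm]
    feasible: bool = True
    infeasible_reasons: list[str] = field(default_factory=list)


@dataclass
class MatchSolution:
    """An (in-progress or complete) multistate atom mapping."""

    states: list[ForceFieldTopology]
    matches: list[AtomMatch]
    options: SearchOptions = field(default_factory=SearchOptions)
    score: "object" = None  # ScoreValue, set by scoring.evaluate_solution

    def __post_init__(self) -> None:
        self.validate()

    @classmethod
    def trusted(cls, states, matches, options) -> "MatchSolution":
        """Construct without re-running the invariant checks — for engine
        internals that guarantee them by construction."""
        obj = object.__new__(cls)
        obj.states = states
        obj.matches = matches
        obj.options = options
        obj.score = None
        return obj

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n_states = len(self.states)
        seen: list[set[int]] = [set() for _ in range(n_states)]
        for m in self.matches:
            if len(m) != n_states:
                raise TopologyError("match tuple length differs from state count")
            for s, e in enumerate(m.entries):
                if e is DUMMY:
                    continue
                if not (0 <= e < len(self.states[s])):
                    raise TopologyError(f"match entry {e} out of range for state {s}")
                if e in seen[s]:
                    raise TopologyError(f"atom {e} of state {s} matched twice")
                seen[s].add(e)
        self._check_bond_preservation()

    def _check_bond_preservation(self) -> None:
        bonds = [t.bond_set() for t in self.states]
        for a in range(len(self.matches)):
            for b in range(a + 1, len(self.matches)):
                ma, mb = self.matches[a], self.matches[b]
                common = [s for s in ma.real_states if s in mb.real_states]
                if len(common) < 2:
                    continue
                have = {s: frozenset((ma[s], mb[s])) in bonds[s] for s in common}
                if len(set(have.values())) > 1:
                    raise TopologyError(
                        f"bond preservation violated between matches {a} and {b}: "
                        f"bonded in states {[s for s, h in have.items() if h]} only"
                    )

    # -- helpers ------------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    def assigned(self, s: int) -> set[int]:
        return {m[s] for m in self.matches if m[s] is not DUMMY}

    def match_of(self, s: int) -> dict[int, int]:
        """atom index in state s -> match-tuple position."""
        return {m[s]: k for k, m in enumerate(self.matches) if m[s] is not DUMMY}

    @property
    def is_complete(self) -> bool:
        return all(len(self.assigned(s)) == len(t) for s, t in enumerate(self.states))

    def real_real_matches(self) -> list[AtomMatch]:
        return [m for m in self.matches if len(m.real_states) >= 2]

    @property
    def n_matched_atoms(self) -> int:
        """Size of the common substructure (multi-real match tuples)."""
        return len(self.real_real_matches())

    def pair_mapping(self, s: int = 0, t: int = 1) -> dict[int, int]:
        return {m[s]: m[t] for m in self.matches
                if m[s] is not DUMMY and m[t] is not DUMMY}

    def classify(self) -> Classification:
        return classify_solution(self.states, self.matches, self.options)

    def completed(self) -> "MatchSolution":
        """Return a copy with every unassigned atom explicitly dummy-matched."""
        n = self.n_states
        matches = list(self.matches)
        for s, top in enumerate(self.states):
            left = sorted(set(range(len(top))) - self.assigned(s))
            for a in left:
                entries = [DUMMY] * n
                entries[s] = a
                matches.append(AtomMatch(tuple(entries)))
        return MatchSolution(self.states, matches, self.options)


# ---------------------------------------------------------------------------
# classification


def classify_solution(states: Sequence[ForceFieldTopology],
                      matches: Sequence[AtomMatch],
                      opts: SearchOptions) -> Classification:
    counts: Counter = Counter()
    terms: list[PerturbedTerm] = []
    cls = Classification(counts, terms)

    tup_of = [
        {m[s]: k for k, m in enumerate(matches) if m[s] is not DUMMY}
        for s in range(len(states))
    ]

    _classify_atoms(states, matches, cls)
    _classify_simple_terms(states, matches, tup_of, BOND, "bond", opts, cls)
    _classify_simple_terms(states, matches, tup_of, ANGLE, "angle", opts, cls)
    _classify_simple_terms(states, matches, tup_of, IMPROPER, "improper", opts, cls)
    if opts.dihedral_match == "all_four_atoms":
        _classify_dihedrals_all_four(states, matches, tup_of, opts, cls)
    else:
        _classify_dihedrals_middle_two(states, matches, tup_of, opts, cls)
    return cls


def _classify_atoms(states, matches, cls: Classification) -> None:
    for k, m in enumerate(matches):
        cls.counts["dummy"] += m.n_dummy
        real = [(s, states[s].atoms[m[s]]) for s in m.real_states]
        if len(real) < 2:
            continue
        ref_s, ref_a = real[0]
        for cat, attr in (("atomtype", "type_id"), ("mass", "mass"), ("charge", "charge")):
            values = _distinct_atom_values(real, cat)
            if len(values) > 1:
                cls.counts[cat] += len(values) - 1
                cls.perturbed_terms.append(PerturbedTerm(
                    cat, "atom", (k,),
                    {s: getattr(a, attr) for s, a in real}))


def _distinct_atom_values(real, category: str) -> list:
    distinct: list[Atom] = []
    idx = {"atomtype": 0, "mass": 1, "charge": 2}[category]
    for _, a in real:
        if not any(atoms_equivalent(a, d)[idx] for d in distinct):
            distinct.append(a)
    return distinct


def _term_lists(top: ForceFieldTopology, kind: str):
    return {BOND: top.bonds, ANGLE: top.angles, DIHEDRAL: top.dihedrals,
            IMPROPER: top.impropers}[kind]


def _canonical_ids(kind: str, ids: tuple[int, ...]) -> tuple[int, ...]:
    if kind == IMPROPER:
        return tuple(sorted(ids))
    return min(ids, ids[::-1])


def _real_states_of(matches, tuple_ids: Sequence[int]) -> list[int]:
    n = len(matches[0]) if matches else 0
    return [s for s in range(n)
            if all(matches[t][s] is not DUMMY for t in tuple_ids)]


def _distinct_params(per_state: dict[int, tuple]) -> int:
    distinct: list[tuple] = []
    for p in per_state.values():
        if not any(params_equal(p, q) for q in distinct):
            distinct.append(p)
    return len(distinct)


def _classify_simple_terms(states, matches, tup_of, kind, category, opts,
                           cls: Classification) -> None:
    """Bonds, angles and impropers: grouped by the mapped atom tuple."""
    groups: dict[tuple[int, ...], dict[int, tuple]] = {}
    for s, top in enumerate(states):
        for term in _term_lists(top, kind):
            idxs, ref = term[:-1], term[-1]
            if any(i not in tup_of[s] for i in idxs):
                continue  # undetermined or dummy-region
            key = _canonical_ids(kind, tuple(tup_of[s][i] for i in idxs))
            groups.setdefault(key, {})[s] = top.resolve(ref)

    for key, present in sorted(groups.items()):
        real_states = _real_states_of(matches, key)
        if len(real_states) < 2:
            continue  # the term exists in one state's (dummy) region only
        present_here = {s: p for s, p in present.items() if s in real_states}
        absent = [s for s in real_states if s not in present_here]
        if absent and present_here:
            per_state = {s: present_here.get(s) for s in real_states}
            if kind == BOND:
                cls.feasible = False
                cls.infeasible_reasons.append(
                    f"bond {key} exists only in states {sorted(present_here)}; "
                    "the search may not create or remove bonds")
                continue
            cls.counts[category] += 1
            cls.perturbed_terms.append(
                PerturbedTerm(category, kind, key, per_state, created_removed=True))
            if not opts.allow_make_break_bonded:
                cls.feasible = False
                cls.infeasible_reasons.append(
                    f"{kind} {key} would be created/removed "
                    "(allow_make_break_bonded is off)")
        elif present_here:
            n_distinct = _distinct_params(present_here)
            if n_distinct > 1:
                cls.counts[category] += n_distinct - 1
                cls.perturbed_terms.append(
                    PerturbedTerm(category, kind, key, dict(present_here)))


def _classify_dihedrals_all_four(states, matches, tup_of, opts,
                                 cls: Classification) -> None:
    groups: dict[tuple[int, ...], dict[int, list[tuple]]] = {}
    for s, top in enumerate(states):
        for i, j, k, l, ref in top.dihedrals:
            if any(x not in tup_of[s] for x in (i, j, k, l)):
                continue
            key = _canonical_ids(DIHEDRAL, tuple(tup_of[s][x] for x in (i, j, k, l)))
            groups.setdefault(key, {}).setdefault(s, []).append(top.resolve(ref))

    for key, present in sorted(groups.items()):
        real_states = _real_states_of(matches, key)
        if len(real_states) < 2:
            continue
        lists = {s: sorted(present.get(s, []), key=_dihedral_sort_key)
                 for s in real_states}
        _compare_dihedral_lists(key, lists, opts, cls,
                                multiplicity_guard=True)


def _classify_dihedrals_middle_two(states, matches, tup_of, opts,
                                   cls: Classification) -> None:
    # A dihedral participates once all four of its atoms belong to the
    # common substructure (multi-real tuples); a dihedral reaching into a
    # dummy branch stays a dummy-region term.  Grouping is by the mapped
    # central bond; groups with not-yet-assigned member dihedrals are
    # deferred so partial classifications stay monotone.
    multi_real = [
        {m[s] for m in matches if m[s] is not DUMMY and len(m.real_states) >= 2}
        for s in range(len(states))
    ]
    groups: dict[tuple[int, int], dict[int, list[tuple]]] = {}
    deferred: set[tuple[int, int]] = set()
    for s, top in enumerate(states):
        for i, j, k, l, ref in top.dihedrals:
            if j not in tup_of[s] or k not in tup_of[s]:
                continue
            key = tuple(sorted((tup_of[s][j], tup_of[s][k])))
            if i not in tup_of[s] or l not in tup_of[s]:
                deferred.add(key)  # outer atom not yet assigned
                continue
            if i not in multi_real[s] or l not in multi_real[s]:
                continue  # dummy-region dihedral
            groups.setdefault(key, {}).setdefault(s, []).append(top.resolve(ref))

    for key, present in sorted(groups.items()):
        if key in deferred:
            continue
        real_states = _real_states_of(matches, key)
        if len(real_states) < 2:
            continue
        lists = {s: sorted(present.get(s, []), key=_dihedral_sort_key)
                 for s in real_states}
        _compare_dihedral_lists(key, lists, opts, cls,
                                multiplicity_guard=False)


def _dihedral_sort_key(p: tuple) -> tuple:
    return (p[2], p[0], p[1])  # multiplicity, phase, force constant


def _compare_dihedral_lists(key, lists: dict[int, list[tuple]], opts,
                            cls: Classification, multiplicity_guard: bool) -> None:
    lengths = {len(v) for v in lists.values()}
    if len(lengths) > 1:
        cls.counts["dihedral"] += 1
        cls.perturbed_terms.append(PerturbedTerm(
            "dihedral", DIHEDRAL, key,
            {s: tuple(v) for s, v in lists.items()}, created_removed=True))
        if not opts.allow_make_break_bonded:
            cls.feasible = False
            cls.infeasible_reasons.append(
                f"dihedral count on {key} differs between states "
                "(allow_make_break_bonded is off)")
        return
    n = lengths.pop()
    if n == 0:
        return
    for pos in range(n):
        per_state = {s: lists[s][pos] for s in lists}
        mults = {p[2] for p in per_state.values()}
        others = {s: p[:2] for s, p in per_state.items()}
        if len(mults) > 1:
            cls.counts["multiplicity"] += len(mults) - 1
            cls.perturbed_terms.append(
                PerturbedTerm("multiplicity", DIHEDRAL, key, dict(per_state)))
            if multiplicity_guard and not opts.allow_multiplicity_change:
                cls.feasible = False
                cls.infeasible_reasons.append(
                    f"dihedral multiplicity on {key} changes "
                    "(allow_multiplicity_change is off)")
        n_distinct = _distinct_params({s: p for s, p in others.items()})
        if n_distinct > 1:
            cls.counts["dihedral"] += n_distinct - 1
            cls.perturbed_terms.append(
                PerturbedTerm("dihedral", DIHEDRAL, key, dict(per_state)))
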