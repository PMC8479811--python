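"""Single-topology perturbation outputs and dummy-atom bookkeeping.

A complete match solution is converted into one union molecule whose atoms
carry per-state parameters: atoms matched between states keep each state's
type/mass/charge, atoms present in only one state become noninteracting
dummies (type ``DUM``, zero charge) in the state where they do not exist.
The bond list is identical across states (the search never creates or
removes bonds); angles, dihedrals and impropers confined to one state's
dummy region keep that state's parameters in both states so the dummy
branch stays geometrically well defined.

Dummy atoms should be anchored to the unperturbed part of the molecule by
three nonredundant bonded interactions; any further term to non-dummy
atoms is redundant and may bias the free energy, so the audit counts the
anchoring terms of every dummy and emits warnings — nothing is removed
automatically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .core import (ANGLE, BOND, DIHEDRAL, DUMMY, IMPROPER, Atom,
                   ForceFieldTopology, SerializationError, TopologyError,
                   canonical_term_key, params_equal)
from .solution import AtomMatch, MatchSolution

log = logging.getLogger(__name__)

DUMMY_TYPE = "DUM"
_KINDS = (BOND, ANGLE, DIHEDRAL, IMPROPER)
_ARITY = {BOND: 2, ANGLE: 3, DIHEDRAL: 4, IMPROPER: 4}
_PREFIX = {BOND: "b", ANGLE: "a", DIHEDRAL: "d", IMPROPER: "i"}


@dataclass
class StateAtom:
    name: str
    type_id: str
    mass: float
    charge: float
    charge_group: int | None
    is_dummy: bool
    orig: int | None  # atom index in that state's input topology


@dataclass
class UnionAtom:
    index: int
    per_state: list[StateAtom]

    @property
    def is_perturbed(self) -> bool:
        ref = self.per_state[0]
        return any(s.is_dummy or s.type_id != ref.type_id or
                   abs(s.mass - ref.mass) > 1e-9 or
                   abs(s.charge - ref.charge) > 1e-9
                   for s in self.per_state)

    @property
    def dummy_states(self) -> list[int]:
        return [k for k, s in enumerate(self.per_state) if s.is_dummy]


@dataclass
class UnionTerm:
    kind: str
    idxs: tuple[int, ...]
    per_state: list[tuple | None]  # None: term absent in that state

    def filled(self) -> list[tuple]:
        """Per-state params with absences replaced by the zero-force-constant
        variant of the present state's geometry."""
        present = next(p for p in self.per_state if p is not None)
        if self.kind == DIHEDRAL:
            zero = (present[0], 0.0, present[2])
        else:
            zero = (present[0], 0.0)
        return [p if p is not None else zero for p in self.per_state]


@dataclass
class PerturbationTopology:
    """Union molecule with per-state parameters (two or more states)."""

    title: str
    n_states: int
    atoms: list[UnionAtom]
    terms: list[UnionTerm]
    exclusions: list[dict[int, set[int]]]
    pairs_14: list[list[tuple[int, int]]]
    state_labels: list[str]
    provenance: MatchSolution | None = None
    dummy_type: str = DUMMY_TYPE

    def validate(self) -> None:
        for ua in self.atoms:
            if all(s.is_dummy for s in ua.per_state):
                raise TopologyError(f"union atom {ua.index} is dummy in every state")
            for k, s in enumerate(ua.per_state):
                if s.is_dummy and abs(s.charge) > 1e-12:
                    raise TopologyError(
                        f"union atom {ua.index} is dummy in state {k} "
                        "but carries a charge")
        n = len(self.atoms)
        for t in self.terms:
            if any(not 0 <= i < n for i in t.idxs):
                raise TopologyError(f"{t.kind} term {t.idxs} out of range")
            if t.kind == BOND and any(p is None for p in t.per_state):
                raise TopologyError(
                    f"bond {t.idxs} absent in one state (bonds may not be "
                    "created or removed)")

    def terms_of(self, kind: str) -> list[UnionTerm]:
        return [t for t in self.terms if t.kind == kind]


class EDSTopology(PerturbationTopology):
    """Reference-state union topology for enveloping distribution sampling:
    all states share the bonded terms; only atom types, masses and charges
    (and dummy designations) switch between states."""

    def validate(self) -> None:
        super().validate()
        for t in self.terms:
            present = [p for p in t.per_state if p is not None]
            for p in present[1:]:
                if not params_equal(p, present[0]):
                    raise TopologyError(
                        f"{t.kind} term {t.idxs} carries perturbed parameters "
                        "— not representable as an EDS reference topology")
            for k, p in enumerate(t.per_state):
                if p is None and not any(
                        self.atoms[i].per_state[k].is_dummy for i in t.idxs):
                    raise TopologyError(
                        f"{t.kind} term {t.idxs} is absent in state {k} "
                        "among real atoms — EDS states must share bonded terms")


def build_pert_topology(sol: MatchSolution, state_a: int = 0,
                        state_b: int = 1) -> PerturbationTopology:
    """Pairwise union topology between two states of a complete solution."""
    if not sol.is_complete:
        raise TopologyError("the match solution is not complete")
    proj = _project(sol, [state_a, state_b])
    pert = _build_union(sol, [state_a, state_b], proj, PerturbationTopology)
    pert.validate()
    return pert


def _project(sol: MatchSolution, states: list[int]) -> list[tuple]:
    """Match tuples restricted to the chosen states, dummy-only rows dropped,
    ordered by first-state then subsequent-state atom indices."""
    rows = []
    for m in sol.matches:
        entries = tuple(m[s] for s in states)
        if all(e is DUMMY for e in entries):
            continue
        rows.append(entries)
    big = 10 ** 9

    def order(row):
        return tuple(big if e is DUMMY else e for e in row)

    rows.sort(key=order)
    return rows


def _build_union(sol: MatchSolution, state_ids: list[int], rows: list[tuple],
                 cls) -> PerturbationTopology:
    tops = [sol.states[s] for s in state_ids]
    n_states = len(state_ids)
    atoms: list[UnionAtom] = []
    uidx = [dict() for _ in range(n_states)]  # orig atom -> union index
    for row in rows:
        k_union = len(atoms)
        real = [(k, e) for k, e in enumerate(row) if e is not DUMMY]
        per_state: list[StateAtom] = []
        for k in range(n_states):
            if row[k] is not DUMMY:
                a = tops[k].atoms[row[k]]
                per_state.append(StateAtom(a.name, a.type_id, a.mass, a.charge,
                                           a.charge_group, False, row[k]))
                uidx[k][row[k]] = k_union
            else:
                ak, ae = real[0]
                a = tops[ak].atoms[ae]
                per_state.append(StateAtom(a.name, DUMMY_TYPE, a.mass, 0.0,
                                           a.charge_group, True, None))
        atoms.append(UnionAtom(k_union, per_state))

    # gather bonded terms; dihedrals may stack several multiplicities per key
    terms: list[UnionTerm] = []
    for kind in _KINDS:
        groups: dict[tuple, list[list[tuple]]] = {}
        for k, top in enumerate(tops):
            for term in getattr(top, kind + "s"):
                idxs, ref = term[:-1], term[-1]
                u = tuple(uidx[k][i] for i in idxs)
                key = canonical_term_key(kind, u)
                if (key, u) not in groups:
                    groups[(key, u)] = [[] for _ in range(n_states)]
                groups[(key, u)][k].append(top.resolve(ref))
        # merge entries that share a canonical key but were recorded with
        # different orientations
        merged: dict[tuple, tuple[tuple, list[list[tuple]]]] = {}
        for (key, u), lists in groups.items():
            if key in merged:
                tgt = merged[key][1]
                for k in range(n_states):
                    tgt[k].extend(lists[k])
            else:
                merged[key] = (u, lists)
        for key in sorted(merged):
            u, lists = merged[key]
            dummy_in = [k for k in range(n_states)
                        if any(atoms[i].per_state[k].is_dummy for i in u)]
            n_max = max(len(v) for v in lists)
            for k in range(n_states):
                lists[k] = sorted(lists[k], key=_dh_sort) + \
                    [None] * (n_max - len(lists[k]))
            for pos in range(n_max):
                per_state: list[tuple | None] = []
                owner = next(lists[k][pos] for k in range(n_states)
                             if lists[k][pos] is not None)
                for k in range(n_states):
                    p = lists[k][pos]
                    if p is None and k in dummy_in:
                        p = owner  # dummy-region term keeps real-state params
                    per_state.append(p)
                terms.append(UnionTerm(kind, u, per_state))

    exclusions, pairs = [], []
    for k, top in enumerate(tops):
        exc: dict[int, set[int]] = {}
        for i, js in top.exclusions.items():
            exc.setdefault(uidx[k][i], set()).update(uidx[k][j] for j in js)
        p14 = sorted((uidx[k][i], uidx[k][j]) for i, j in top.pairs_14)
        exclusions.append(exc)
        pairs.append(p14)
    # dummy atoms inherit the exclusions of their real-state atom
    for ua in atoms:
        for k in ua.dummy_states:
            real_k = next(q for q in range(n_states)
                          if not ua.per_state[q].is_dummy)
            for i, js in exclusions[real_k].items():
                for j in js:
                    if ua.index in (i, j):
                        exclusions[k].setdefault(i, set()).add(j)

    labels = [tops[k].title for k in range(n_states)]
    title = " -> ".join(labels) if n_states == 2 else " / ".join(labels)
    return cls(title, n_states, atoms, terms, exclusions, pairs, labels,
               provenance=sol)


def _dh_sort(p: tuple) -> tuple:
    return (p[2], p[0], p[1]) if len(p) == 3 else tuple(p)


# ---------------------------------------------------------------------------
# restriction back to an end state


def restrict_to_state(pert: PerturbationTopology, k: int) -> ForceFieldTopology:
    """End-state topology: dummy atoms of state ``k`` and all terms touching
    them (or absent in ``k``) are dropped; atoms return to their original
    order."""
    keep = [ua for ua in pert.atoms if not ua.per_state[k].is_dummy]
    keep.sort(key=lambda ua: ua.per_state[k].orig)
    remap = {ua.index: i for i, ua in enumerate(keep)}
    atoms = []
    for i, ua in enumerate(keep):
        s = ua.per_state[k]
        atoms.append(Atom(i, s.name, s.type_id, s.mass, s.charge, s.charge_group))
    top = ForceFieldTopology(pert.state_labels[k], atoms)
    counters: dict[str, int] = {}
    for t in pert.terms:
        if t.per_state[k] is None or any(i not in remap for i in t.idxs):
            continue
        idxs = tuple(remap[i] for i in t.idxs)
        vals = t.per_state[k]
        ref = None
        for r, p in top.param_tables.items():
            if p == (t.kind, *vals):
                ref = r
                break
        if ref is None:
            counters[t.kind] = counters.get(t.kind, 0) + 1
            ref = f"{_PREFIX[t.kind]}{counters[t.kind]}"
            top.param_tables[ref] = (t.kind, *vals)
        getattr(top, t.kind + "s").append((*idxs, ref))
    for i, js in pert.exclusions[k].items():
        if i in remap:
            kept = {remap[j] for j in js if j in remap}
            if kept:
                top.exclusions[remap[i]] = kept
    top.pairs_14 = [(remap[i], remap[j]) for i, j in pert.pairs_14[k]
                    if i in remap and j in remap]
    top.validate()
    return top


# ---------------------------------------------------------------------------
# dummy audit


@dataclass
class DummyAtomReport:
    index: int
    name: str
    n_anchor_terms: int
    by_kind: dict[str, int]
    redundant: int
    under_anchored: bool

    @property
    def warning(self) -> bool:
        return self.redundant > 0 or self.under_anchored


@dataclass
class DummyAudit:
    reports: list[DummyAtomReport] = field(default_factory=list)

    @property
    def warnings(self) -> list[str]:
        out = []
        for r in self.reports:
            if r.redundant:
                out.append(
                    f"dummy atom {r.name} ({r.index}) has {r.n_anchor_terms} "
                    f"bonded interactions with unperturbed atoms: "
                    f"{r.redundant} redundant term(s) — consider manual removal")
            if r.under_anchored:
                out.append(
                    f"dummy atom {r.name} ({r.index}) is anchored by only "
                    f"{r.n_anchor_terms} bonded interaction(s); three "
                    "nonredundant terms are required for proper sampling")
        return out

    @property
    def has_warnings(self) -> bool:
        return bool(self.warnings)


#: A dummy needs exactly this many nonredundant anchoring terms.
N_ANCHORS_REQUIRED = 3


def audit_dummies(pert: PerturbationTopology) -> DummyAudit:
    """Count, for every atom that is a dummy in some state, the bonded
    interactions connecting it to unperturbed (never-dummy) atoms.  Terms
    beyond the three nonredundant anchors are flagged as redundant; a dummy
    reached only through other dummy atoms (zero anchors) is anchored via
    its branch and not flagged."""
    pert.validate()
    never_dummy = {ua.index for ua in pert.atoms if not ua.dummy_states}
    audit = DummyAudit()
    for ua in pert.atoms:
        if not ua.dummy_states:
            continue
        by_kind = {k: 0 for k in _KINDS}
        for t in pert.terms:
            if ua.index in t.idxs and \
                    all(i in never_dummy for i in t.idxs if i != ua.index):
                by_kind[t.kind] += 1
        n = sum(by_kind.values())
        redundant = max(0, n - N_ANCHORS_REQUIRED)
        under = 0 < n < N_ANCHORS_REQUIRED
        name = next(s.name for s in ua.per_state if not s.is_dummy)
        audit.reports.append(DummyAtomReport(ua.index, name, n, by_kind,
                                             redundant, under))
    for msg in audit.warnings:
        log.warning("%s", msg)
    return audit
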