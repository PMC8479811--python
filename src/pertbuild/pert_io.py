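"""Serialization of perturbation and EDS topologies.

GROMACS dialect: one topology whose ``[ atoms ]`` lines carry the standard
dual-state columns (type/charge/mass followed by typeB/chargeB/massB) and
whose bonded lines carry A- then B-state parameters.

GROMOS dialect: a reference solute topology (state-A parameters on the
union atom set, dummies typed ``DUM`` with zero charge) plus a perturbation
file: PERTATOMPARAM lists the perturbed atoms with state-A and state-B
type/mass/charge; PERTBONDSTRETCH / PERTBONDANGLE / PERTPROPERDIH /
PERTIMPROPERDIH list perturbed terms with both states' parameter values.
Multistate (EDS) output uses an MPERTATOM block with per-state type and
charge columns; the GROMOS dialect cannot express per-state masses, which
is reported as a serialization error.  Soft-core parameters are simulation
input, not topology content, and are never written.
"""

from __future__ import annotations

from pathlib import Path

from .core import (ANGLE, BOND, DIHEDRAL, IMPROPER, Atom, ForceFieldTopology,
                   ParseError, SerializationError, canonical_term_key,
                   params_equal)
from .pert_builder import (DUMMY_TYPE, PerturbationTopology, EDSTopology,
                           StateAtom, UnionAtom, UnionTerm, _ARITY, _PREFIX)
from .topology_io import read_topology, write_topology, _read_gromacs

_PERT_BLOCK = {BOND: "PERTBONDSTRETCH", ANGLE: "PERTBONDANGLE",
               DIHEDRAL: "PERTPROPERDIH", IMPROPER: "PERTIMPROPERDIH"}


def end_state_topology(pert: PerturbationTopology, k: int) -> ForceFieldTopology:
    """Full union-atom topology carrying state ``k``'s parameters (dummy
    atoms kept, with the noninteracting dummy type and zero charge)."""
    atoms = []
    for ua in pert.atoms:
        s = ua.per_state[k]
        name = next(st.name for st in ua.per_state if not st.is_dummy)
        atoms.append(Atom(ua.index, name, s.type_id, s.mass, s.charge,
                          s.charge_group))
    top = ForceFieldTopology(pert.state_labels[k], atoms)
    counters: dict[str, int] = {}
    for t in pert.terms:
        vals = t.filled()[k]
        ref = None
        for r, p in top.param_tables.items():
            if p == (t.kind, *vals):
                ref = r
                break
        if ref is None:
            counters[t.kind] = counters.get(t.kind, 0) + 1
            ref = f"{_PREFIX[t.kind]}{counters[t.kind]}"
            top.param_tables[ref] = (t.kind, *vals)
        getattr(top, t.kind + "s").append((*t.idxs, ref))
    top.exclusions = {i: set(js) for i, js in pert.exclusions[0].items()}
    top.pairs_14 = list(pert.pairs_14[0])
    top.validate()
    return top


# ---------------------------------------------------------------------------
# pairwise perturbation files


def write_perturbation(pert: PerturbationTopology, prefix, dialect: str) -> None:
    """GROMACS: ``<prefix>.top`` with A/B columns.  GROMOS: reference
    ``<prefix>.top`` plus ``<prefix>.ptp`` perturbation blocks."""
    pert.validate()
    if pert.n_states != 2:
        raise SerializationError("pairwise writer requires exactly two states; "
                                 "use write_eds_topology for multistate output")
    prefix = Path(prefix)
    if dialect == "gromacs":
        _write_gromacs_pert(pert, prefix.with_suffix(".top"))
    elif dialect == "gromos":
        write_topology(end_state_topology(pert, 0), prefix.with_suffix(".top"),
                       "gromos")
        _write_gromos_ptp(pert, prefix.with_suffix(".ptp"))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_gromacs_pert(pert: PerturbationTopology, path: Path) -> None:
    out = ["[ moleculetype ]", "; name nrexcl", "PERT 0", "", "[ atoms ]",
           "; nr type resnr residue atom cgnr charge mass typeB chargeB massB"]
    for ua in pert.atoms:
        a, b = ua.per_state
        name = next(s.name for s in ua.per_state if not s.is_dummy)
        cg = a.charge_group if a.charge_group is not None else ua.index + 1
        out.append(f"{ua.index + 1} {a.type_id} 1 MOL {name} {cg} "
                   f"{a.charge:.6f} {a.mass:.5f} "
                   f"{b.type_id} {b.charge:.6f} {b.mass:.5f}")

    def fmt(vals):
        return " ".join(f"{int(v)}" if isinstance(v, int) else f"{v:.6f}"
                        for v in vals)

    out += ["", "[ bonds ]"]
    for t in pert.terms_of(BOND):
        a, b = t.filled()
        out.append(" ".join(str(i + 1) for i in t.idxs) + f" 1 {fmt(a)} {fmt(b)}")
    out += ["", "[ angles ]"]
    for t in pert.terms_of(ANGLE):
        a, b = t.filled()
        out.append(" ".join(str(i + 1) for i in t.idxs) + f" 1 {fmt(a)} {fmt(b)}")
    out += ["", "[ dihedrals ]"]
    for t in pert.terms_of(DIHEDRAL):
        a, b = t.filled()
        out.append(" ".join(str(i + 1) for i in t.idxs) + f" 1 {fmt(a)} {fmt(b)}")
    for t in pert.terms_of(IMPROPER):
        a, b = t.filled()
        out.append(" ".join(str(i + 1) for i in t.idxs) + f" 2 {fmt(a)} {fmt(b)}")
    if pert.pairs_14[0]:
        out += ["", "[ pairs ]"]
        out += [f"{i + 1} {j + 1} 1" for i, j in pert.pairs_14[0]]
    if any(pert.exclusions[0].values()):
        out += ["", "[ exclusions ]"]
        for i in sorted(pert.exclusions[0]):
            js = sorted(pert.exclusions[0][i])
            if js:
                out.append(" ".join(str(x + 1) for x in [i, *js]))
    path.write_text("\n".join(out) + "\n")


def _write_gromos_ptp(pert: PerturbationTopology, path: Path) -> None:
    out = [f"TITLE\nperturbation: {pert.title}\nEND"]
    perturbed = [ua for ua in pert.atoms if ua.is_perturbed]
    lines = [str(len(perturbed)),
             "# NR NAME TYPEA MASSA CHARGEA TYPEB MASSB CHARGEB"]
    for ua in perturbed:
        a, b = ua.per_state
        name = next(s.name for s in ua.per_state if not s.is_dummy)
        lines.append(f"{ua.index + 1} {name} {a.type_id} {a.mass:.5f} "
                     f"{a.charge:.6f} {b.type_id} {b.mass:.5f} {b.charge:.6f}")
    out.append("PERTATOMPARAM\n%s\nEND" % "\n".join(lines))
    for kind in (BOND, ANGLE, DIHEDRAL, IMPROPER):
        rows = []
        for t in pert.terms_of(kind):
            a, b = t.filled()
            if not params_equal(a, b):
                vals = " ".join(_num(v) for v in (*a, *b))
                rows.append(" ".join(str(i + 1) for i in t.idxs) + " " + vals)
        out.append(f"{_PERT_BLOCK[kind]}\n{len(rows)}\n" +
                   ("\n".join(rows) + "\n" if rows else "") + "END")
    path.write_text("\n".join(out) + "\n")


def _num(v) -> str:
    return str(int(v)) if isinstance(v, int) else f"{v:.6f}"


def read_perturbation(prefix, dialect: str,
                      dummy_type: str = DUMMY_TYPE) -> PerturbationTopology:
    prefix = Path(prefix)
    if dialect == "gromacs":
        top_a, top_b = _read_gromacs(prefix.with_suffix(".top"), allow_b_state=True)
        for t in (top_a, top_b):
            t.validate()
        return pert_from_end_states([top_a, top_b], dummy_type)
    if dialect == "gromos":
        top_a = read_topology(prefix.with_suffix(".top"), "gromos")
        top_b = _apply_gromos_ptp(top_a, prefix.with_suffix(".ptp"))
        return pert_from_end_states([top_a, top_b], dummy_type)
    raise ValueError(f"unknown dialect {dialect!r}")


def _apply_gromos_ptp(top_a: ForceFieldTopology, path: Path) -> ForceFieldTopology:
    from .topology_io import _gromos_blocks

    if not path.is_file():
        raise IOError(f"no such perturbation file: {path}")
    blocks = _gromos_blocks(path)
    import copy

    top_b = copy.deepcopy(top_a)
    if "PERTATOMPARAM" in blocks:
        body = blocks["PERTATOMPARAM"]
        for line in body[1:1 + int(body[0])]:
            tok = line.split()
            idx = int(tok[0]) - 1
            if not 0 <= idx < len(top_b.atoms):
                raise ParseError(f"{path}: PERTATOMPARAM references atom {tok[0]}")
            a = top_b.atoms[idx]
            a.type_id, a.mass, a.charge = tok[5], float(tok[6]), float(tok[7])
    for kind, block in _PERT_BLOCK.items():
        if block not in blocks:
            continue
        body = blocks[block]
        arity = _ARITY[kind]
        nval = 3 if kind == DIHEDRAL else 2
        for line in body[1:1 + int(body[0])]:
            tok = line.split()
            idxs = tuple(int(x) - 1 for x in tok[:arity])
            vals_b = [float(x) for x in tok[arity + nval:arity + 2 * nval]]
            if kind == DIHEDRAL:
                vals_b = [vals_b[0], vals_b[1], int(vals_b[2])]
            key = canonical_term_key(kind, idxs)
            terms = getattr(top_b, kind + "s")
            hit = None
            for pos, t in enumerate(terms):
                if canonical_term_key(kind, t[:-1]) == key:
                    hit = pos
                    break
            if hit is None:
                raise ParseError(f"{path}: {block} entry {idxs} has no "
                                 "matching term in the reference topology")
            ref = f"{_PREFIX[kind]}pt{len(top_b.param_tables)}"
            top_b.param_tables[ref] = (kind, *vals_b)
            terms[hit] = (*terms[hit][:-1], ref)
    return top_b


def pert_from_end_states(tops: list[ForceFieldTopology],
                         dummy_type: str = DUMMY_TYPE) -> PerturbationTopology:
    """Rebuild a PerturbationTopology/EDSTopology from end-state topologies
    that share one union atom ordering (as read back from disk)."""
    n_states = len(tops)
    n_atoms = len(tops[0])
    if any(len(t) != n_atoms for t in tops):
        raise ParseError("end-state topologies differ in atom count")
    atoms = []
    orig_counters = [0] * n_states
    for i in range(n_atoms):
        per_state = []
        for k, t in enumerate(tops):
            a = t.atoms[i]
            dummy = a.type_id == dummy_type
            orig = None
            if not dummy:
                orig = orig_counters[k]
                orig_counters[k] += 1
            per_state.append(StateAtom(a.name, a.type_id, a.mass, a.charge,
                                       a.charge_group, dummy, orig))
        atoms.append(UnionAtom(i, per_state))

    terms: list[UnionTerm] = []
    for kind in (BOND, ANGLE, DIHEDRAL, IMPROPER):
        groups: dict[tuple, list[list[tuple]]] = {}
        order: list[tuple] = []
        for k, t in enumerate(tops):
            for term in getattr(t, kind + "s"):
                key = canonical_term_key(kind, term[:-1])
                if key not in groups:
                    groups[key] = [[] for _ in range(n_states)]
                    order.append((key, tuple(term[:-1])))
                groups[key][k].append(t.resolve(term[-1]))
        for key, idxs in order:
            lists = groups[key]
            n_max = max(len(v) for v in lists)
            for k in range(n_states):
                lists[k] = sorted(lists[k], key=_mult_sort) + \
                    [None] * (n_max - len(lists[k]))
            for pos in range(n_max):
                terms.append(UnionTerm(kind, idxs,
                                       [lists[k][pos] for k in range(n_states)]))

    cls = EDSTopology if n_states > 2 else PerturbationTopology
    pert = cls(
        title=" / ".join(t.title for t in tops),
        n_states=n_states, atoms=atoms, terms=terms,
        exclusions=[{i: set(js) for i, js in tops[0].exclusions.items()}
                    for _ in range(n_states)],
        pairs_14=[list(tops[0].pairs_14) for _ in range(n_states)],
        state_labels=[t.title for t in tops], dummy_type=dummy_type)
    pert.validate()
    return pert


def _mult_sort(p: tuple) -> tuple:
    return (p[2], p[0], p[1]) if len(p) == 3 else tuple(p)


def pert_equal(p: PerturbationTopology, q: PerturbationTopology) -> bool:
    """Semantic equality on the content the file formats carry: per-state
    atom parameters and dummy flags, per-state (filled) term parameters,
    reference-state exclusions and 1-4 pairs."""
    if p.n_states != q.n_states or len(p.atoms) != len(q.atoms):
        return False
    for ua, ub in zip(p.atoms, q.atoms):
        for sa, sb in zip(ua.per_state, ub.per_state):
            if (sa.type_id != sb.type_id or sa.is_dummy != sb.is_dummy or
                    abs(sa.mass - sb.mass) > 1e-6 or
                    abs(sa.charge - sb.charge) > 1e-6):
                return False

    def term_map(pt):
        out = {}
        for t in pt.terms:
            key = (t.kind, canonical_term_key(t.kind, t.idxs))
            out.setdefault(key, []).append(
                tuple(tuple(round(x, 9) for x in v) for v in t.filled()))
        return {k: sorted(v) for k, v in out.items()}

    if term_map(p) != term_map(q):
        return False
    exc_p = {(i, j) for i, js in p.exclusions[0].items() for j in js}
    exc_q = {(i, j) for i, js in q.exclusions[0].items() for j in js}
    if exc_p != exc_q:
        return False
    return sorted(p.pairs_14[0]) == sorted(q.pairs_14[0])


# ---------------------------------------------------------------------------
# EDS (multistate) files


def write_eds_topology(eds: PerturbationTopology, prefix, dialect: str) -> None:
    """GROMACS: one topology file per state on the shared union atom list
    (``<prefix>_state<k>.top``).  GROMOS: reference topology plus an
    MPERTATOM multistate perturbation block."""
    eds.validate()
    prefix = Path(prefix)
    if dialect == "gromacs":
        for k in range(eds.n_states):
            write_topology(end_state_topology(eds, k),
                           Path(f"{prefix}_state{k}.top"), "gromacs")
        return
    if dialect != "gromos":
        raise ValueError(f"unknown dialect {dialect!r}")
    for ua in eds.atoms:
        masses = {round(s.mass, 9) for s in ua.per_state}
        if len(masses) > 1:
            raise SerializationError(
                f"union atom {ua.index}: per-state masses {sorted(masses)} — "
                "the GROMOS MPERTATOM block cannot express mass perturbations")
    write_topology(end_state_topology(eds, 0), prefix.with_suffix(".top"),
                   "gromos")
    perturbed = [ua for ua in eds.atoms if ua.is_perturbed]
    lines = ["# NJLA NPTB", f"{len(perturbed)} {eds.n_states}",
             "# state identifiers",
             " ".join(l.split()[0] for l in eds.state_labels)]
    for ua in perturbed:
        name = next(s.name for s in ua.per_state if not s.is_dummy)
        row = [str(ua.index + 1), name]
        for s in ua.per_state:
            row += [s.type_id, f"{s.charge:.6f}"]
        lines.append(" ".join(row))
    text = f"TITLE\nEDS: {eds.title}\nEND\nMPERTATOM\n" + "\n".join(lines) + "\nEND\n"
    prefix.with_suffix(".ptp").write_text(text)


def read_eds_topology(prefix, dialect: str, n_states: int,
                      dummy_type: str = DUMMY_TYPE) -> EDSTopology:
    prefix = Path(prefix)
    if dialect == "gromacs":
        tops = [read_topology(Path(f"{prefix}_state{k}.top"), "gromacs")
                for k in range(n_states)]
        return pert_from_end_states(tops, dummy_type)
    if dialect != "gromos":
        raise ValueError(f"unknown dialect {dialect!r}")
    from .topology_io import _gromos_blocks
    import copy

    ref = read_topology(prefix.with_suffix(".top"), "gromos")
    blocks = _gromos_blocks(prefix.with_suffix(".ptp"))
    if "MPERTATOM" not in blocks:
        raise ParseError(f"{prefix}.ptp: missing MPERTATOM block")
    body = blocks["MPERTATOM"]
    n_pert, n_from_file = (int(x) for x in body[0].split())
    if n_from_file != n_states:
        raise ParseError(f"{prefix}.ptp: file declares {n_from_file} states, "
                         f"{n_states} requested")
    tops = [copy.deepcopy(ref) for _ in range(n_states)]
    for k, t in enumerate(tops):
        t.title = body[1].split()[k] if len(body[1].split()) == n_states else t.title
    for line in body[2:2 + n_pert]:
        tok = line.split()
        idx = int(tok[0]) - 1
        for k in range(n_states):
            a = tops[k].atoms[idx]
            a.type_id = tok[2 + 2 * k]
            a.charge = float(tok[3 + 2 * k])
    return pert_from_end_states(tops, dummy_type)
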