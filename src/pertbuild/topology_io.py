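"""Reading and writing molecular topologies in two engine dialects.

GROMOS11 solute block format: TITLE / ATOMTYPENAME / SOLUTEATOM /
BONDSTRETCHTYPE+BOND(H) / BONDANGLEBENDTYPE+BONDANGLE(H) /
IMPDIHEDRALTYPE+IMPDIHEDRAL(H) / TORSDIHEDRALTYPE+DIHEDRAL(H) blocks, each
closed by END, '#' starting a comment line.  Exclusions and 1-4 neighbor
lists ride on the SOLUTEATOM lines.

GROMACS topology format: [ moleculetype ] / [ atoms ] / [ bonds ] /
[ pairs ] / [ angles ] / [ dihedrals ] / [ exclusions ] sections with ';'
comments; ``#include`` directives are inlined textually and simple
``#define`` macros substituted before parsing (an unresolvable include is
an error, never silently skipped).  Bonded parameters are written inline on
the term lines (funct 1 bonds/angles, funct 1 proper dihedrals with
multiplicity, funct 2 impropers).  Only the (first) solute molecule block
is read; solvent content is ignored.

Both dialects are 1-based on disk; the in-memory topology is 0-based —
conversion happens only here.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import numpy as np

from .core import (ANGLE, BOND, DIHEDRAL, IMPROPER, Atom, CoordinateSet,
                   ForceFieldTopology, ParseError, SerializationError)

_GROMOS_KIND_BLOCKS = {
    BOND: ("BONDSTRETCHTYPE", ("BOND", "BONDH"), 2),
    ANGLE: ("BONDANGLEBENDTYPE", ("BONDANGLE", "BONDANGLEH"), 3),
    IMPROPER: ("IMPDIHEDRALTYPE", ("IMPDIHEDRAL", "IMPDIHEDRALH"), 4),
    DIHEDRAL: ("TORSDIHEDRALTYPE", ("DIHEDRAL", "DIHEDRALH"), 4),
}
_KIND_NPARAM = {BOND: 2, ANGLE: 2, IMPROPER: 2, DIHEDRAL: 3}
_KIND_PREFIX = {BOND: "b", ANGLE: "a", DIHEDRAL: "d", IMPROPER: "i"}


def read_topology(path, dialect: str) -> ForceFieldTopology:
    """Parse one solute topology in the named dialect."""
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such topology file: {path}")
    if dialect == "gromos":
        top = _read_gromos(path)
    elif dialect == "gromacs":
        top = _read_gromacs(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        top.validate()
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    top.source_dialect = dialect
    return top


def write_topology(top: ForceFieldTopology, path, dialect: str) -> None:
    top.validate()
    if dialect == "gromos":
        text = _format_gromos(top)
    elif dialect == "gromacs":
        text = _format_gromacs(top)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    Path(path).write_text(text)


# ---------------------------------------------------------------------------
# GROMOS block format


def _gromos_blocks(path: Path) -> dict[str, list[str]]:
    blocks: dict[str, list[str]] = {}
    name = None
    body: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if name is None:
            name = line.split()[0]
            body = []
        elif line == "END":
            blocks[name] = body
            name = None
        else:
            body.append(line)
    if name is not None:
        raise ParseError(f"{path}: block {name!r} not closed by END")
    return blocks

_GROMOS_KNOWN = {"TITLE", "ATOMTYPENAME", "SOLUTEATOM", "PHYSICALCONSTANTS",
                 "TOPVERSION", "RESNAME", "LJPARAMETERS", "SOLUTEMOLECULES",
                 "TEMPERATUREGROUPS", "PRESSUREGROUPS"} | {
    b for spec in _GROMOS_KIND_BLOCKS.values() for b in (spec[0], *spec[1])}


def _read_gromos(path: Path) -> ForceFieldTopology:
    blocks = _gromos_blocks(path)
    unknown = set(blocks) - _GROMOS_KNOWN
    if unknown:
        raise ParseError(f"{path}: unknown block(s) {sorted(unknown)}")
    if "SOLUTEATOM" not in blocks:
        raise ParseError(f"{path}: missing SOLUTEATOM block")

    title = " ".join(blocks.get("TITLE", ["untitled"]))
    type_names = []
    if "ATOMTYPENAME" in blocks:
        body = blocks["ATOMTYPENAME"]
        type_names = body[1:1 + int(body[0])]

    body = blocks["SOLUTEATOM"]
    n_atoms = int(body[0])
    atoms, exclusions, pairs = [], {}, []
    if len(body) - 1 != n_atoms:
        raise ParseError(f"{path}: SOLUTEATOM announces {n_atoms} atoms, "
                         f"{len(body) - 1} lines found")
    for line in body[1:]:
        tok = line.split()
        try:
            idx = int(tok[0]) - 1
            name = tok[2]
            iac = int(tok[3]) - 1
            mass, charge = float(tok[4]), float(tok[5])
            cgc = int(tok[6])
            nex = int(tok[7])
            exc = [int(x) - 1 for x in tok[8:8 + nex]]
            n14 = int(tok[8 + nex])
            p14 = [int(x) - 1 for x in tok[9 + nex:9 + nex + n14]]
        except (IndexError, ValueError) as exc_:
            raise ParseError(f"{path}: bad SOLUTEATOM line: {line!r}") from exc_
        if not (0 <= iac < len(type_names)):
            raise ParseError(f"{path}: atom {idx + 1} references atom type "
                             f"{iac + 1} outside ATOMTYPENAME")
        atoms.append(Atom(idx, name, type_names[iac], mass, charge, cgc))
        if exc:
            exclusions[idx] = set(exc)
        pairs.extend((idx, j) for j in p14)

    top = ForceFieldTopology(title, atoms, exclusions=exclusions, pairs_14=pairs)
    for kind, (type_block, term_blocks, arity) in _GROMOS_KIND_BLOCKS.items():
        types: list[tuple] = []
        if type_block in blocks:
            body = blocks[type_block]
            for line in body[1:1 + int(body[0])]:
                vals = [float(x) for x in line.split()]
                if kind == DIHEDRAL:
                    vals = [vals[1], vals[0], int(vals[2])]  # CP PD NP -> phase,k,mult
                else:
                    vals = [vals[1], vals[0]]                # K X0 -> x0, k
                types.append((kind, *vals))
        terms = []
        for bname in term_blocks:
            if bname not in blocks:
                continue
            body = blocks[bname]
            for line in body[1:1 + int(body[0])]:
                tok = [int(x) for x in line.split()]
                idxs, tref = [t - 1 for t in tok[:arity]], tok[arity] - 1
                if not (0 <= tref < len(types)):
                    raise ParseError(f"{path}: {bname} line {line!r} references "
                                     f"missing type {tref + 1}")
                ref = f"{_KIND_PREFIX[kind]}{tref + 1}"
                top.param_tables[ref] = types[tref]
                terms.append((*idxs, ref))
        getattr(top, kind + "s").extend(terms)
    return top


def _param_index(top: ForceFieldTopology, kind: str):
    """Deterministic (types, ref->index) tables for one term kind."""
    terms = getattr(top, kind + "s")
    types: list[tuple] = []
    index: dict[str, int] = {}
    for t in terms:
        ref = t[-1]
        if ref not in index:
            index[ref] = len(types)
            types.append(top.param_tables[ref])
    return types, index


def _format_gromos(top: ForceFieldTopology) -> str:
    out = [f"TITLE\n{top.title}\nEND"]
    type_names: list[str] = []
    for a in top.atoms:
        if a.type_id not in type_names:
            type_names.append(a.type_id)
    out.append("ATOMTYPENAME\n# NRATT\n%d\n%s\nEND"
               % (len(type_names), "\n".join(type_names)))

    lines = ["# NRP", str(len(top.atoms)),
             "# ATNM MRES PANM IAC MASS CG CGC INE INE14"]
    for a in top.atoms:
        if a.charge_group is None:
            raise SerializationError(
                f"GROMOS dialect requires charge groups (atom {a.index} has none)")
        exc = sorted(top.exclusions.get(a.index, ()))
        p14 = sorted(j for i, j in top.pairs_14 if i == a.index)
        lines.append(" ".join(map(str, [
            a.index + 1, 1, a.name, type_names.index(a.type_id) + 1,
            f"{a.mass:.5f}", f"{a.charge:.6f}", a.charge_group,
            len(exc), *[e + 1 for e in exc], len(p14), *[p + 1 for p in p14]])))
    out.append("SOLUTEATOM\n%s\nEND" % "\n".join(lines))

    for kind, (type_block, term_blocks, arity) in _GROMOS_KIND_BLOCKS.items():
        types, index = _param_index(top, kind)
        tlines = [str(len(types))]
        for p in types:
            vals = p[1:]
            if kind == DIHEDRAL:
                tlines.append(f"{vals[1]:.6f} {vals[0]:.6f} {int(vals[2])}")
            else:
                tlines.append(f"{vals[1]:.6f} {vals[0]:.6f}")
        out.append(f"{type_block}\n%s\nEND" % "\n".join(tlines))
        terms = getattr(top, kind + "s")
        blines = [str(len(terms))]
        for t in terms:
            blines.append(" ".join(str(i + 1) for i in t[:-1]) +
                          f" {index[t[-1]] + 1}")
        out.append(f"{term_blocks[0]}\n%s\nEND" % "\n".join(blines))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# GROMACS section format


def _preprocess_gromacs(path: Path) -> list[tuple[str, str]]:
    """Inline #include, apply #define macros; returns (source-tag, line)."""
    defines: dict[str, str] = {}
    out: list[tuple[str, str]] = []

    def feed(p: Path) -> None:
        if not p.is_file():
            raise ParseError(f"unresolved include: {p}")
        for lineno, raw in enumerate(p.read_text().splitlines(), 1):
            line = raw.split(";")[0].rstrip()
            if not line.strip():
                continue
            stripped = line.strip()
            if stripped.startswith("#include"):
                target = stripped.split(None, 1)[1].strip().strip('"<>')
                feed((p.parent / target))
                continue
            if stripped.startswith("#define"):
                parts = stripped.split(None, 2)
                defines[parts[1]] = parts[2] if len(parts) > 2 else ""
                continue
            if stripped.startswith("#"):
                raise ParseError(f"{p}:{lineno}: unsupported directive {stripped!r}")
            if defines:
                toks = [defines.get(t, t) for t in line.split()]
                line = " ".join(toks)
            out.append((f"{p}:{lineno}", line))

    feed(path)
    return out


_GMX_IGNORED = {"defaults", "atomtypes", "system", "molecules", "bondtypes",
                "angletypes", "dihedraltypes", "pairtypes", "nonbond_params"}
_GMX_KNOWN = _GMX_IGNORED | {"moleculetype", "atoms", "bonds", "pairs",
                             "angles", "dihedrals", "exclusions"}


def _gromacs_sections(path: Path):
    sections: list[tuple[str, list[tuple[str, str]]]] = []
    current = None
    for tag, line in _preprocess_gromacs(path):
        s = line.strip()
        if s.startswith("[") and s.endswith("]"):
            name = s[1:-1].strip().lower()
            if name not in _GMX_KNOWN:
                raise ParseError(f"{tag}: unknown section [ {name} ]")
            current = (name, [])
            sections.append(current)
        else:
            if current is None:
                raise ParseError(f"{tag}: content outside any section: {s!r}")
            current[1].append((tag, s))
    return sections


def _read_gromacs(path: Path, allow_b_state: bool = False):
    sections = _gromacs_sections(path)
    # keep only the first molecule block's sections
    per_name: dict[str, list] = {}
    n_moltypes = 0
    for name, body in sections:
        if name == "moleculetype":
            n_moltypes += 1
        if n_moltypes > 1 or name in _GMX_IGNORED:
            continue
        per_name.setdefault(name, []).extend(body)
    if "atoms" not in per_name:
        raise ParseError(f"{path}: no [ atoms ] section")

    title = "untitled"
    if per_name.get("moleculetype"):
        title = per_name["moleculetype"][0][1].split()[0]

    atoms, b_atoms = [], []
    for tag, line in per_name["atoms"]:
        tok = line.split()
        try:
            idx = int(tok[0]) - 1
            type_id, name = tok[1], tok[4]
            cgnr = int(tok[5])
            charge, mass = float(tok[6]), float(tok[7])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{tag}: bad atom line {line!r}") from exc
        atoms.append(Atom(idx, name, type_id, mass, charge, cgnr))
        if len(tok) > 8:
            if not allow_b_state:
                raise ParseError(
                    f"{tag}: B-state columns present; this is a perturbation "
                    "topology — use read_perturbation")
            b_atoms.append(Atom(idx, name, tok[8], float(tok[10]),
                                float(tok[9]), cgnr))
        elif allow_b_state:
            b_atoms.append(Atom(idx, name, type_id, mass, charge, cgnr))

    top = ForceFieldTopology(title, atoms)
    b_top = ForceFieldTopology(title, b_atoms) if allow_b_state else None
    counters: dict[str, int] = {}

    def add_param(t: ForceFieldTopology, kind: str, vals: tuple) -> str:
        for ref, p in t.param_tables.items():
            if p == (kind, *vals):
                return ref
        counters[kind] = counters.get(kind, 0) + 1
        ref = f"{_KIND_PREFIX[kind]}{counters[kind]}"
        while ref in t.param_tables:
            counters[kind] += 1
            ref = f"{_KIND_PREFIX[kind]}{counters[kind]}"
        t.param_tables[ref] = (kind, *vals)
        return ref

    def parse_terms(section: str, arity: int):
        for tag, line in per_name.get(section, []):
            tok = line.split()
            try:
                idxs = [int(x) - 1 for x in tok[:arity]]
                funct = int(tok[arity])
                vals = [float(x) for x in tok[arity + 1:]]
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{tag}: bad [ {section} ] line {line!r}") from exc
            yield tag, idxs, funct, vals

    for tag, idxs, funct, vals in parse_terms("bonds", 2):
        a_vals, b_vals = _split_ab(tag, vals, 2, allow_b_state)
        top.bonds.append((*idxs, add_param(top, BOND, tuple(a_vals))))
        if b_top is not None:
            b_top.bonds.append((*idxs, add_param(b_top, BOND, tuple(b_vals))))
    for tag, idxs, funct, vals in parse_terms("angles", 3):
        a_vals, b_vals = _split_ab(tag, vals, 2, allow_b_state)
        top.angles.append((*idxs, add_param(top, ANGLE, tuple(a_vals))))
        if b_top is not None:
            b_top.angles.append((*idxs, add_param(b_top, ANGLE, tuple(b_vals))))
    for tag, idxs, funct, vals in parse_terms("dihedrals", 4):
        if funct in (1, 9):
            kind, nv = DIHEDRAL, 3
        elif funct == 2:
            kind, nv = IMPROPER, 2
        else:
            raise ParseError(f"{tag}: unsupported dihedral funct {funct}")
        a_vals, b_vals = _split_ab(tag, vals, nv, allow_b_state)
        if kind == DIHEDRAL:
            a_vals, b_vals = [*a_vals[:2], int(a_vals[2])], [*b_vals[:2], int(b_vals[2])]
        lst = top.dihedrals if kind == DIHEDRAL else top.impropers
        lst.append((*idxs, add_param(top, kind, tuple(a_vals))))
        if b_top is not None:
            lst_b = b_top.dihedrals if kind == DIHEDRAL else b_top.impropers
            lst_b.append((*idxs, add_param(b_top, kind, tuple(b_vals))))
    for tag, line in per_name.get("pairs", []):
        tok = line.split()
        top.pairs_14.append((int(tok[0]) - 1, int(tok[1]) - 1))
    for tag, line in per_name.get("exclusions", []):
        tok = [int(x) - 1 for x in line.split()]
        top.exclusions.setdefault(tok[0], set()).update(tok[1:])
    if b_top is not None:
        b_top.pairs_14 = list(top.pairs_14)
        b_top.exclusions = {k: set(v) for k, v in top.exclusions.items()}
        return top, b_top
    return top


def _split_ab(tag, vals, n, allow_b):
    if len(vals) == n:
        return vals, vals
    if len(vals) == 2 * n and allow_b:
        return vals[:n], vals[n:]
    raise ParseError(f"{tag}: expected {n} parameter value(s), got {len(vals)}")


def _format_gromacs(top: ForceFieldTopology) -> str:
    out = ["[ moleculetype ]", "; name nrexcl", f"{_molname(top)} 0", "",
           "[ atoms ]", "; nr type resnr residue atom cgnr charge mass"]
    for a in top.atoms:
        out.append(f"{a.index + 1} {a.type_id} 1 MOL {a.name} "
                   f"{a.charge_group if a.charge_group is not None else a.index + 1} "
                   f"{a.charge:.6f} {a.mass:.5f}")
    out += ["", "[ bonds ]"]
    for i, j, ref in top.bonds:
        x0, k = top.resolve(ref)
        out.append(f"{i + 1} {j + 1} 1 {x0:.6f} {k:.6f}")
    out += ["", "[ angles ]"]
    for i, j, k_, ref in top.angles:
        x0, k = top.resolve(ref)
        out.append(f"{i + 1} {j + 1} {k_ + 1} 1 {x0:.6f} {k:.6f}")
    out += ["", "[ dihedrals ]", "; propers funct 1, impropers funct 2"]
    for i, j, k_, l, ref in top.dihedrals:
        ph, k, m = top.resolve(ref)
        out.append(f"{i + 1} {j + 1} {k_ + 1} {l + 1} 1 {ph:.6f} {k:.6f} {int(m)}")
    for i, j, k_, l, ref in top.impropers:
        x0, k = top.resolve(ref)
        out.append(f"{i + 1} {j + 1} {k_ + 1} {l + 1} 2 {x0:.6f} {k:.6f}")
    if top.pairs_14:
        out += ["", "[ pairs ]"]
        out += [f"{i + 1} {j + 1} 1" for i, j in top.pairs_14]
    if any(top.exclusions.values()):
        out += ["", "[ exclusions ]"]
        for i in sorted(top.exclusions):
            exc = sorted(top.exclusions[i])
            if exc:
                out.append(" ".join(str(x + 1) for x in [i, *exc]))
    return "\n".join(out) + "\n"


def _molname(top: ForceFieldTopology) -> str:
    token = top.title.split()[0] if top.title.split() else "MOL"
    return token


# ---------------------------------------------------------------------------
# coordinates


def read_coordinates(path, fmt: str | None = None) -> CoordinateSet:
    """Read a PDB or GRO coordinate file; positions returned in nm."""
    import MDAnalysis as mda

    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such coordinate file: {path}")
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty coordinate file")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("pdb", "gro"):
        raise ValueError(f"unsupported coordinate format {fmt!r}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(os.fspath(path), format=fmt, to_guess=())
            positions = np.asarray(u.atoms.positions, dtype=float)
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(positions) == 0:
        raise ParseError(f"{path}: no atoms found")
    return CoordinateSet(positions / 10.0)  # MDAnalysis uses angstrom
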