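"""United-atom toy systems for exercising the perturbation builder.

Every fixture is a deterministic, internally consistent force-field
topology built from invented but fixed parameter constants (they stand in
for united-atom force-field values; CHn groups are single particles).
Several fixtures come with a synthetic 3D conformation used by the
RMSD-based solution ranking.  The registry covers the demonstration
systems: methanol/ethane, the lysine side chain and its trimethylated and
acetylated forms, alkane chains and (methylated) cycloalkanes, fused /
bridged / spiro polycycles, and a halogen-substituted congeneric ligand
pair sharing an aromatic scaffold.

``random_topology`` generates small random attributed molecules (trees)
for exhaustive-oracle comparisons.
"""

from __future__ import annotations

import numpy as np

from .core import Atom, CoordinateSet, ForceFieldTopology

# invented fixed force-field constants -------------------------------------
PARAMS = {
    # bonds: (b0 nm, kb)
    "b_cc":    ("bond", 0.1530, 334720.0),
    "b_co":    ("bond", 0.1435, 377400.0),
    "b_oh":    ("bond", 0.0972, 464895.0),
    "b_cn":    ("bond", 0.1470, 376560.0),
    "b_nh":    ("bond", 0.1000, 464895.0),
    "b_nc3":   ("bond", 0.1480, 376560.0),
    "b_ncam":  ("bond", 0.1330, 418400.0),
    "b_codb":  ("bond", 0.1230, 502080.0),
    "b_car":   ("bond", 0.1390, 418400.0),
    "b_char":  ("bond", 0.1090, 464895.0),
    "b_cf":    ("bond", 0.1360, 418400.0),
    # angles: (theta0 deg, kt)
    "a_ccc":   ("angle", 111.0, 530.0),
    "a_coh":   ("angle", 109.5, 450.0),
    "a_cnh":   ("angle", 109.5, 425.0),
    "a_cnc3":  ("angle", 109.5, 450.0),
    "a_cncam": ("angle", 120.0, 560.0),
    "a_hncam": ("angle", 118.0, 560.0),
    "a_nco":   ("angle", 121.0, 560.0),
    "a_ncc":   ("angle", 115.0, 560.0),
    "a_occ":   ("angle", 124.0, 560.0),
    "a_ar":    ("angle", 120.0, 560.0),
    "a_sub":   ("angle", 120.0, 505.0),
    # proper dihedrals: (phase deg, k, multiplicity)
    "d_ccc":   ("dihedral", 0.0, 5.92, 3),
    "d_nh":    ("dihedral", 0.0, 1.00, 3),
    "d_ncam":  ("dihedral", 180.0, 3.00, 6),
    "d_amo":   ("dihedral", 180.0, 3.00, 2),
    "d_amc":   ("dihedral", 180.0, 1.00, 2),
    # impropers: (xi0 deg, k)
    "i_plan":  ("improper", 0.0, 167.36),
}

MASS = {"CH3": 15.035, "CH2": 14.027, "CH1": 13.019, "CR1": 13.019,
        "C": 12.011, "OA": 15.9994, "O": 15.9994, "N": 14.0067,
        "NL": 14.0067, "NT": 14.0067, "H": 1.008, "HC": 1.008, "F": 18.9984}


def _top(title, atom_rows, bonds, angles=(), dihedrals=(), impropers=()):
    """Build a topology from name-based term lists."""
    names = [r[0] for r in atom_rows]
    index = {n: i for i, n in enumerate(names)}
    atoms = [Atom(i, n, t, MASS[t], q, i + 1)
             for i, (n, t, q) in enumerate(atom_rows)]
    top = ForceFieldTopology(title, atoms)
    for row in bonds:
        *ats, ref = row
        top.bonds.append((*(index[a] for a in ats), ref))
        top.param_tables[ref] = PARAMS[ref]
    for row in angles:
        *ats, ref = row
        top.angles.append((*(index[a] for a in ats), ref))
        top.param_tables[ref] = PARAMS[ref]
    for row in dihedrals:
        *ats, ref = row
        top.dihedrals.append((*(index[a] for a in ats), ref))
        top.param_tables[ref] = PARAMS[ref]
    for row in impropers:
        *ats, ref = row
        top.impropers.append((*(index[a] for a in ats), ref))
        top.param_tables[ref] = PARAMS[ref]
    # standard exclusions: first and second bonded neighbors
    adj = {i: set() for i in range(len(atoms))}
    for i, j, _ in top.bonds:
        adj[i].add(j)
        adj[j].add(i)
    for i in range(len(atoms)):
        exc = set(adj[i])
        for j in adj[i]:
            exc |= adj[j]
        exc.discard(i)
        top.exclusions[i] = {j for j in exc if j > i}
    top.validate()
    return top


def _ring(title, n, atom_type="CH2", extra_atoms=(), extra_bonds=(),
          extra_angles=(), ring_types=None):
    """Cycloalkane-style ring with optional substituents; angles cover
    every bonded two-path."""
    names = [f"C{i + 1}" for i in range(n)]
    types = ring_types or [atom_type] * n
    rows = [(names[i], types[i], 0.0) for i in range(n)]
    rows += list(extra_atoms)
    bonds = [(names[i], names[(i + 1) % n], "b_cc") for i in range(n)]
    bonds += list(extra_bonds)
    angles = _all_two_path_angles(rows, bonds, default="a_ccc",
                                  override=dict(extra_angles))
    return _top(title, rows, bonds, angles)


def _all_two_path_angles(rows, bonds, default, override=None):
    override = override or {}
    adj: dict[str, set[str]] = {r[0]: set() for r in rows}
    for a, b, _ in bonds:
        adj[a].add(b)
        adj[b].add(a)
    out = []
    for center in sorted(adj):
        nbrs = sorted(adj[center])
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                key = (nbrs[x], center, nbrs[y])
                out.append((*key, override.get(key, default)))
    return out


# ---------------------------------------------------------------------------
# the named fixtures


def _methanol():
    top = _top("methanol",
               [("C1", "CH3", 0.176), ("O", "OA", -0.574), ("H", "H", 0.398)],
               bonds=[("C1", "O", "b_co"), ("O", "H", "b_oh")],
               angles=[("C1", "O", "H", "a_coh")])
    coords = CoordinateSet(np.array([
        [0.0, 0.0, 0.0], [0.1435, 0.0, 0.0], [0.1760, 0.0916, 0.0]]))
    return top, coords


def _ethane():
    top = _top("ethane", [("C1", "CH3", 0.0), ("C2", "CH3", 0.0)],
               bonds=[("C1", "C2", "b_cc")])
    coords = CoordinateSet(np.array([[0.0, 0.0, 0.0], [0.1530, 0.0, 0.0]]))
    return top, coords


_CHAIN_ATOMS = [("CB", "CH2", 0.0), ("CG", "CH2", 0.0), ("CD", "CH2", 0.0)]
_CHAIN_BONDS = [("CB", "CG", "b_cc"), ("CG", "CD", "b_cc"), ("CD", "CE", "b_cc")]
_CHAIN_ANGLES = [("CB", "CG", "CD", "a_ccc"), ("CG", "CD", "CE", "a_ccc"),
                 ("CD", "CE", "NZ", "a_ccc")]
_CHAIN_DIHEDRALS = [("CB", "CG", "CD", "CE", "d_ccc"),
                    ("CG", "CD", "CE", "NZ", "d_ccc")]
_CHAIN_XYZ = [[0.0, 0.0, 0.0], [0.15, 0.0, 0.0], [0.30, 0.0, 0.0],
              [0.45, 0.0, 0.0], [0.60, 0.0, 0.0]]


def _lysine_side():
    top = _top(
        "lysine",
        _CHAIN_ATOMS + [("CE", "CH2", 0.127), ("NZ", "NL", 0.129),
                        ("H1", "H", 0.248), ("H2", "H", 0.248), ("H3", "H", 0.248)],
        bonds=_CHAIN_BONDS + [("CE", "NZ", "b_cn"), ("NZ", "H1", "b_nh"),
                              ("NZ", "H2", "b_nh"), ("NZ", "H3", "b_nh")],
        angles=_CHAIN_ANGLES + [("CE", "NZ", "H1", "a_cnh"),
                                ("CE", "NZ", "H2", "a_cnh"),
                                ("CE", "NZ", "H3", "a_cnh")],
        dihedrals=_CHAIN_DIHEDRALS + [("CD", "CE", "NZ", "H1", "d_nh"),
                                      ("CD", "CE", "NZ", "H2", "d_nh"),
                                      ("CD", "CE", "NZ", "H3", "d_nh")])
    coords = CoordinateSet(np.array(_CHAIN_XYZ + [
        [0.65, 0.094, 0.0], [0.65, -0.047, 0.081], [0.65, -0.047, -0.081]]))
    return top, coords


def _trimethyllysine_side():
    top = _top(
        "trimethyllysine",
        _CHAIN_ATOMS + [("CE", "CH2", 0.127), ("NZ", "NT", -0.093),
                        ("C1", "CH3", 0.322), ("C2", "CH3", 0.322),
                        ("C3", "CH3", 0.322)],
        bonds=_CHAIN_BONDS + [("CE", "NZ", "b_cn"), ("NZ", "C1", "b_nc3"),
                              ("NZ", "C2", "b_nc3"), ("NZ", "C3", "b_nc3")],
        angles=_CHAIN_ANGLES + [("CE", "NZ", "C1", "a_cnc3"),
                                ("CE", "NZ", "C2", "a_cnc3"),
                                ("CE", "NZ", "C3", "a_cnc3")],
        dihedrals=_CHAIN_DIHEDRALS + [("CD", "CE", "NZ", "C1", "d_nh"),
                                      ("CD", "CE", "NZ", "C2", "d_nh"),
                                      ("CD", "CE", "NZ", "C3", "d_nh")])
    coords = CoordinateSet(np.array(_CHAIN_XYZ + [
        [0.66, 0.104, 0.01], [0.66, -0.052, 0.092], [0.66, -0.052, -0.092]]))
    return top, coords


def _acetyllysine_side():
    top = _top(
        "acetyllysine",
        _CHAIN_ATOMS + [("CE", "CH2", 0.0), ("NZ", "N", -0.31),
                        ("HN", "H", 0.31), ("CH", "C", 0.38),
                        ("OC", "O", -0.38), ("CM", "CH3", 0.0)],
        bonds=_CHAIN_BONDS + [("CE", "NZ", "b_cn"), ("NZ", "HN", "b_nh"),
                              ("NZ", "CH", "b_ncam"), ("CH", "OC", "b_codb"),
                              ("CH", "CM", "b_cc")],
        angles=_CHAIN_ANGLES + [("CE", "NZ", "HN", "a_cnh"),
                                ("CE", "NZ", "CH", "a_cncam"),
                                ("HN", "NZ", "CH", "a_hncam"),
                                ("NZ", "CH", "OC", "a_nco"),
                                ("NZ", "CH", "CM", "a_ncc"),
                                ("OC", "CH", "CM", "a_occ")],
        dihedrals=_CHAIN_DIHEDRALS + [("CD", "CE", "NZ", "HN", "d_nh"),
                                      ("CD", "CE", "NZ", "CH", "d_ncam"),
                                      ("CE", "NZ", "CH", "OC", "d_amo"),
                                      ("CE", "NZ", "CH", "CM", "d_amc")],
        impropers=[("NZ", "CE", "CH", "HN", "i_plan"),
                   ("CH", "NZ", "OC", "CM", "i_plan")])
    coords = CoordinateSet(np.array(_CHAIN_XYZ + [
        [0.65, 0.094, 0.0], [0.67, -0.10, 0.0],
        [0.80, -0.12, 0.0], [0.86, -0.26, 0.0]]))
    return top, coords


def _hexane():
    rows = [("C1", "CH3", 0.0)] + [(f"C{i}", "CH2", 0.0) for i in range(2, 6)] \
        + [("C6", "CH3", 0.0)]
    bonds = [(f"C{i}", f"C{i + 1}", "b_cc") for i in range(1, 6)]
    angles = [(f"C{i}", f"C{i + 1}", f"C{i + 2}", "a_ccc") for i in range(1, 5)]
    dihedrals = [(f"C{i}", f"C{i + 1}", f"C{i + 2}", f"C{i + 3}", "d_ccc")
                 for i in range(1, 4)]
    return _top("hexane", rows, bonds, angles, dihedrals), None


def _methylcyclohexane(positions=(1,)):
    n = 6
    ring_types = ["CH1" if (i + 1) in positions else "CH2" for i in range(n)]
    extra_atoms = [(f"CM{p}", "CH3", 0.0) for p in positions]
    extra_bonds = [(f"C{p}", f"CM{p}", "b_cc") for p in positions]
    name = "methylcyclohexane" if len(positions) == 1 else \
        "dimethylcyclohexane" + "".join(str(p) for p in positions)
    return _ring(name, n, extra_atoms=extra_atoms, extra_bonds=extra_bonds,
                 ring_types=ring_types), None


def _fused_bicycle():
    """Decalin-like: two six-rings sharing the C1-C6 edge."""
    rows = [("C1", "CH1", 0.0)] + [(f"C{i}", "CH2", 0.0) for i in range(2, 6)] \
        + [("C6", "CH1", 0.0)] + [(f"C{i}", "CH2", 0.0) for i in range(7, 11)]
    bonds = [("C1", "C2", "b_cc"), ("C2", "C3", "b_cc"), ("C3", "C4", "b_cc"),
             ("C4", "C5", "b_cc"), ("C5", "C6", "b_cc"), ("C6", "C1", "b_cc"),
             ("C6", "C7", "b_cc"), ("C7", "C8", "b_cc"), ("C8", "C9", "b_cc"),
             ("C9", "C10", "b_cc"), ("C10", "C1", "b_cc")]
    angles = _all_two_path_angles(rows, bonds, default="a_ccc")
    return _top("decalin", rows, bonds, angles), None


def _bridged_bicycle():
    """Bicyclo[2.2.2]octane: two bridgeheads joined by three 2-atom bridges."""
    rows = [("B1", "CH1", 0.0), ("B2", "CH1", 0.0)] + \
        [(f"C{i}", "CH2", 0.0) for i in range(1, 7)]
    bonds = [("B1", "C1", "b_cc"), ("C1", "C2", "b_cc"), ("C2", "B2", "b_cc"),
             ("B1", "C3", "b_cc"), ("C3", "C4", "b_cc"), ("C4", "B2", "b_cc"),
             ("B1", "C5", "b_cc"), ("C5", "C6", "b_cc"), ("C6", "B2", "b_cc")]
    angles = _all_two_path_angles(rows, bonds, default="a_ccc")
    return _top("bicyclooctane", rows, bonds, angles), None


def _spiro_bicycle():
    """Spiro[4.4]nonane: two five-rings sharing exactly one atom."""
    rows = [("S", "C", 0.0)] + [(f"C{i}", "CH2", 0.0) for i in range(1, 9)]
    bonds = [("S", "C1", "b_cc"), ("C1", "C2", "b_cc"), ("C2", "C3", "b_cc"),
             ("C3", "C4", "b_cc"), ("C4", "S", "b_cc"),
             ("S", "C5", "b_cc"), ("C5", "C6", "b_cc"), ("C6", "C7", "b_cc"),
             ("C7", "C8", "b_cc"), ("C8", "S", "b_cc")]
    angles = _all_two_path_angles(rows, bonds, default="a_ccc")
    return _top("spirononane", rows, bonds, angles), None


def _cyclopentane():
    return _ring("cyclopentane", 5), None


def _hf_ligand(sub: str):
    """Aromatic six-ring scaffold with one substituted position carrying
    either a hydrogen or a fluorine."""
    rows = [(f"C{i}", "CR1", 0.0) for i in range(1, 6)]
    if sub == "H":
        rows += [("C6", "C", -0.14), ("X", "HC", 0.14)]
        sub_bond = ("C6", "X", "b_char")
        title = "ligandH"
    else:
        rows += [("C6", "C", 0.25), ("X", "F", -0.25)]
        sub_bond = ("C6", "X", "b_cf")
        title = "ligandF"
    bonds = [(f"C{i}", f"C{i % 6 + 1}", "b_car") for i in range(1, 7)]
    bonds.append(sub_bond)
    angles = _all_two_path_angles(rows, bonds, default="a_ar")
    angles = [(a, c, b, ("a_sub" if "X" in (a, b) else ref))
              for a, c, b, ref in angles]
    return _top(title, rows, bonds, angles), None


_REGISTRY = {
    "methanol_ua": _methanol,
    "ethane_ua": _ethane,
    "lysine_side": _lysine_side,
    "trimethyllysine_side": _trimethyllysine_side,
    "acetyllysine_side": _acetyllysine_side,
    "hexane": _hexane,
    "cyclohexane": lambda: (_ring("cyclohexane", 6), None),
    "cyclopentane": _cyclopentane,
    "methylcyclohexane": lambda: _methylcyclohexane((1,)),
    "dimethylcyclohexane_12": lambda: _methylcyclohexane((1, 2)),
    "dimethylcyclohexane_13": lambda: _methylcyclohexane((1, 3)),
    "dimethylcyclohexane_14": lambda: _methylcyclohexane((1, 4)),
    "fused_bicycle": _fused_bicycle,
    "bridged_bicycle": _bridged_bicycle,
    "spiro_bicycle": _spiro_bicycle,
    "ligand_h": lambda: _hf_ligand("H"),
    "ligand_f": lambda: _hf_ligand("F"),
}

#: Congeneric series used for the multistate scaffold demonstration.
SERIES = {"hf_ligand_series": ("ligand_h", "ligand_f")}


def fixture_names() -> list[str]:
    return sorted(_REGISTRY)


def make_fixture(name: str):
    """(ForceFieldTopology, CoordinateSet | None) for a registered fixture."""
    if name in SERIES:
        raise KeyError(
            f"{name!r} is a series; use make_series. Known fixtures: "
            f"{', '.join(fixture_names())}")
    if name not in _REGISTRY:
        raise KeyError(f"unknown fixture {name!r}; known fixtures: "
                       f"{', '.join(fixture_names())}")
    return _REGISTRY[name]()


def make_series(name: str) -> list[ForceFieldTopology]:
    if name not in SERIES:
        raise KeyError(f"unknown series {name!r}; known: {sorted(SERIES)}")
    return [make_fixture(n)[0] for n in SERIES[name]]


# ---------------------------------------------------------------------------
# random attributed molecules (for exhaustive-oracle comparisons)

_RAND_TYPES = [("CH3", 15.035), ("CH2", 14.027), ("OA", 15.9994), ("NL", 14.0067)]
_RAND_CHARGES = [-0.2, 0.0, 0.2, 0.4]
_RAND_BONDS = ["b_cc", "b_co"]
_RAND_ANGLES = ["a_ccc", "a_coh"]


def random_topology(rng: np.random.Generator, n_atoms: int,
                    title: str = "random") -> ForceFieldTopology:
    """Random connected attributed molecule: a uniform random labeled tree
    with random atom types/charges and bond/angle parameters drawn from two
    parameter classes; angles cover every bonded two-path."""
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rows = []
    for i in range(n_atoms):
        t, _ = _RAND_TYPES[rng.integers(len(_RAND_TYPES))]
        q = _RAND_CHARGES[rng.integers(len(_RAND_CHARGES))]
        rows.append((f"A{i + 1}", t, q))
    bonds = []
    for i in range(1, n_atoms):
        j = int(rng.integers(i))  # random recursive tree
        ref = _RAND_BONDS[rng.integers(len(_RAND_BONDS))]
        bonds.append((f"A{j + 1}", f"A{i + 1}", ref))
    angles = []
    for a, c, b, _ in _all_two_path_angles(rows, bonds, default="a_ccc"):
        angles.append((a, c, b, _RAND_ANGLES[rng.integers(len(_RAND_ANGLES))]))
    return _top(title, rows, bonds, angles)
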