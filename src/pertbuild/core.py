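"""Engine-neutral force-field topology containers.

A :class:`ForceFieldTopology` holds one solute molecule: its atoms (type,
mass, partial charge, charge group), its bonded terms (bonds, angles,
proper and improper dihedrals), exclusions and 1-4 pairs, and a table of
numeric force-field parameters referenced by the bonded terms.  Both file
dialects (GROMOS11 block format and GROMACS topology sections) are read
into and written from this one form; atom indices are 0-based internally
and converted to 1-based only at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Sentinel marking "matched to a noninteracting dummy" in an atom match.
DUMMY = None

#: Relative tolerance for comparing resolved force-field parameter values.
PARAM_RTOL = 1e-9
#: Absolute tolerance for comparing partial charges (printed-precision round-off).
CHARGE_ATOL = 1e-6
#: Absolute tolerance for comparing atomic masses.
MASS_ATOL = 1e-6


class TopologyError(ValueError):
    """Invalid topology content (violated invariant, dangling index, ...)."""


class ParseError(TopologyError):
    """Malformed input file; the message names the offending line."""


class SerializationError(TopologyError):
    """The requested dialect cannot represent the object."""


@dataclass
class Atom:
    """One interaction site (possibly a united atom such as CH3)."""

    index: int
    name: str
    type_id: str
    mass: float
    charge: float
    charge_group: int | None = None

    def validate(self) -> None:
        if not self.type_id:
            raise TopologyError(f"atom {self.index}: empty type_id")
        if self.mass < 0:
            raise TopologyError(f"atom {self.index}: negative mass {self.mass}")


# Parameter kinds: param_tables maps ref -> (kind, values...).  Values are
#   bond:     (b0 [nm], kb)
#   angle:    (theta0 [deg], kt)
#   dihedral: (phase [deg], k, multiplicity:int)
#   improper: (xi0 [deg], k)
BOND, ANGLE, DIHEDRAL, IMPROPER = "bond", "angle", "dihedral", "improper"


@dataclass
class ForceFieldTopology:
    title: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, str]] = field(default_factory=list)
    angles: list[tuple[int, int, int, str]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int, str]] = field(default_factory=list)
    impropers: list[tuple[int, int, int, int, str]] = field(default_factory=list)
    exclusions: dict[int, set[int]] = field(default_factory=dict)
    pairs_14: list[tuple[int, int]] = field(default_factory=list)
    param_tables: dict[str, tuple] = field(default_factory=dict)
    source_dialect: str | None = None

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n = len(self.atoms)
        if n == 0:
            raise TopologyError("topology has no atoms")
        for i, a in enumerate(self.atoms):
            if a.index != i:
                raise TopologyError(
                    f"atom indices must be contiguous from 0; atom {i} has index {a.index}"
                )
            a.validate()
        for kind, terms, arity in (
            (BOND, self.bonds, 2),
            (ANGLE, self.angles, 3),
            (DIHEDRAL, self.dihedrals, 4),
            (IMPROPER, self.impropers, 4),
        ):
            for t in terms:
                idxs, ref = t[:-1], t[-1]
                if len(set(idxs)) != arity:
                    raise TopologyError(f"{kind} term repeats an atom: {t}")
                for i in idxs:
                    if not (0 <= i < n):
                        raise TopologyError(f"{kind} term {t}: atom index {i} out of range")
                if ref not in self.param_tables:
                    raise TopologyError(f"{kind} term {t}: unresolved param ref {ref!r}")
                if self.param_tables[ref][0] != kind:
                    raise TopologyError(
                        f"{kind} term {t}: param ref {ref!r} is of kind "
                        f"{self.param_tables[ref][0]!r}"
                    )
        for i, exc in self.exclusions.items():
            if not (0 <= i < n) or any(not (0 <= j < n) for j in exc):
                raise TopologyError(f"exclusion list of atom {i} references a missing atom")
        for i, j in self.pairs_14:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise TopologyError(f"invalid 1-4 pair ({i}, {j})")

    # -- parameter resolution ----------------------------------------------
    def resolve(self, ref: str) -> tuple:
        """Numeric parameter values (kind stripped) for a param ref."""
        return self.param_tables[ref][1:]

    def bond_set(self) -> set[frozenset[int]]:
        return {frozenset((i, j)) for i, j, _ in self.bonds}

    def total_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    def __len__(self) -> int:  # number of atoms
        return len(self.atoms)


def params_equal(p: Sequence[float], q: Sequence[float]) -> bool:
    """Resolved numeric parameter equality (relative tolerance ``PARAM_RTOL``).

    Integer entries (dihedral multiplicities) are compared exactly.
    """
    if len(p) != len(q):
        return False
    for a, b in zip(p, q):
        if isinstance(a, int) or isinstance(b, int):
            if int(a) != int(b):
                return False
        elif not math.isclose(a, b, rel_tol=PARAM_RTOL, abs_tol=1e-300):
            return False
    return True


def atoms_equivalent(a: Atom, b: Atom) -> tuple[bool, bool, bool]:
    """(same type, same mass, same charge) under the comparison tolerances."""
    return (
        a.type_id == b.type_id,
        math.isclose(a.mass, b.mass, abs_tol=MASS_ATOL),
        math.isclose(a.charge, b.charge, abs_tol=CHARGE_ATOL),
    )


@dataclass
class CoordinateSet:
    """Per-atom positions in nm, in the atom order of the paired topology."""

    positions: np.ndarray  # (n_atoms, 3)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise TopologyError("positions must be an (n, 3) array")
        if not np.all(np.isfinite(self.positions)):
            raise TopologyError("positions contain non-finite values")

    def validate_against(self, top: ForceFieldTopology) -> None:
        if len(self.positions) != len(top.atoms):
            raise TopologyError(
                f"coordinate set has {len(self.positions)} positions for a "
                f"{len(top.atoms)}-atom topology"
            )

    def __len__(self) -> int:
        return len(self.positions)


def semantically_equal(a: ForceFieldTopology, b: ForceFieldTopology) -> bool:
    """Field-by-field semantic equality of two topologies.

    Atom names, types, masses, charges and charge groups must agree; bonded
    terms must cover the same index tuples with equal resolved parameters
    (labels are irrelevant); exclusions and 1-4 pairs must agree as sets.
    """
    if len(a) != len(b):
        return False
    for x, y in zip(a.atoms, b.atoms):
        t, m, q = atoms_equivalent(x, y)
        if not (t and m and q) or x.name != y.name:
            return False
        if (x.charge_group or 0) != (y.charge_group or 0):
            return False
    for kind in (BOND, ANGLE, DIHEDRAL, IMPROPER):
        if _term_map(a, kind) != _term_map(b, kind):
            return False
    if _norm_exclusions(a) != _norm_exclusions(b):
        return False
    if {frozenset(p) for p in a.pairs_14} != {frozenset(p) for p in b.pairs_14}:
        return False
    return True


def _terms(top: ForceFieldTopology, kind: str) -> list[tuple]:
    return {BOND: top.bonds, ANGLE: top.angles, DIHEDRAL: top.dihedrals,
            IMPROPER: top.impropers}[kind]


def canonical_term_key(kind: str, idxs: Sequence[int]) -> tuple:
    """Direction-insensitive key for a bonded term's atom tuple.

    Bonds/angles/dihedrals may be listed in either direction; impropers are
    compared on their atom set (ordering conventions differ between sources).
    """
    idxs = tuple(idxs)
    if kind == IMPROPER:
        return tuple(sorted(idxs))
    rev = idxs[::-1]
    return min(idxs, rev)


def _term_map(top: ForceFieldTopology, kind: str) -> dict[tuple, tuple]:
    out: dict[tuple, tuple] = {}
    for t in _terms(top, kind):
        key = canonical_term_key(kind, t[:-1])
        vals = tuple(round(v, 12) if isinstance(v, float) else v
                     for v in top.resolve(t[-1]))
        if kind == DIHEDRAL:
            # several dihedrals (multiplicities) may share one atom tuple
            out.setdefault(key, ())
            out[key] = tuple(sorted(out[key] + (vals,)))
        else:
            out[key] = vals
    return out


def _norm_exclusions(top: ForceFieldTopology) -> set[frozenset[int]]:
    out = set()
    for i, exc in top.exclusions.items():
        for j in exc:
            out.add(frozenset((i, j)))
    return out
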