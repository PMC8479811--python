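"""Penalty weights and matching-policy switches.

``ScoreSpec`` holds the user-defined penalty weights: one weight per kind of
individual perturbation (atom type, mass, charge, bonds, angles, proper and
improper dihedrals, dihedral multiplicity) plus the dominant per-dummy-atom
weight.  A category may instead be forbidden outright (infinite penalty).
``SearchOptions`` holds the matching-policy switches: how rings may be
matched, how dihedrals are paired, whether bonded terms other than bonds
may be created/removed, and search bookkeeping limits.

Both are serializable from one flat key-value config file (YAML mapping,
one option per line).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Callable

import yaml

RING_POLICIES = ("complete_individual_rings", "complete_only")
RING_NONRING_POLICIES = ("two_bonded_atoms", "one_atom", "none")
DIHEDRAL_MATCH_MODES = ("all_four_atoms", "middle_two_atoms")

#: Penalty categories a ScoreSpec can weight or forbid.
CATEGORIES = ("dummy", "atomtype", "mass", "charge", "bond", "angle",
              "dihedral", "improper", "multiplicity")


@dataclass(frozen=True)
class ScoreSpec:
    """Penalty weights; the default maximizes the number of matched atoms.

    The dummy weight strictly dominates every parameter-mismatch weight, so
    the default score primarily minimizes dummies (equivalently, maximizes
    matched atoms) and secondarily minimizes parameter perturbations.  With
    ``lexicographic=True`` (default) solutions are compared on the exact
    key ``(dummy count, weighted mismatch total)`` rather than a single
    float, avoiding weight-magnitude artifacts.
    """

    w_dummy: float = 1000.0
    w_atomtype: float = 1.0
    w_mass: float = 1.0
    w_charge: float = 1.0
    w_bond: float = 1.0
    w_angle: float = 1.0
    w_dihedral: float = 1.0
    w_improper: float = 1.0
    w_multiplicity: float = 1.0
    forbid: frozenset[str] = frozenset()
    lexicographic: bool = True
    custom_score: Callable[[dict[str, int]], float] | None = None

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name.startswith("w_") and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")
        bad = set(self.forbid) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown forbid categories: {sorted(bad)}")

    def weight(self, category: str) -> float:
        return getattr(self, f"w_{category}")


def eds_score_spec(**overrides) -> ScoreSpec:
    """Default multistate spec: bonded-term perturbations are forbidden
    (atom type / mass / charge switching remains allowed), the setting used
    to generate enveloping-distribution-sampling reference topologies."""
    base = ScoreSpec(forbid=frozenset({"bond", "angle", "dihedral",
                                       "improper", "multiplicity"}))
    return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class SearchOptions:
    ring_policy: str = "complete_individual_rings"
    ring_nonring_policy: str = "two_bonded_atoms"
    dihedral_match: str = "all_four_atoms"
    allow_multiplicity_change: bool = False
    allow_make_break_bonded: bool = False
    max_solutions: int = 100
    enumerate_all_best: bool | None = None  # None: on for pairwise, off for multistate
    max_nodes: int = 2_000_000
    prune: bool = True
    ring_size_cap: int = 12

    def __post_init__(self) -> None:
        if self.ring_policy not in RING_POLICIES:
            raise ValueError(f"ring_policy must be one of {RING_POLICIES}")
        if self.ring_nonring_policy not in RING_NONRING_POLICIES:
            raise ValueError(f"ring_nonring_policy must be one of {RING_NONRING_POLICIES}")
        if self.dihedral_match not in DIHEDRAL_MATCH_MODES:
            raise ValueError(f"dihedral_match must be one of {DIHEDRAL_MATCH_MODES}")
        if self.max_solutions < 1 or self.max_nodes < 1:
            raise ValueError("max_solutions and max_nodes must be positive")

    @property
    def ring_partial_budget(self) -> int:
        return {"two_bonded_atoms": 2, "one_atom": 1, "none": 0}[self.ring_nonring_policy]


def load_config(path) -> tuple[ScoreSpec, SearchOptions]:
    """Read a flat key-value config file into (ScoreSpec, SearchOptions).

    Keys are field names of either dataclass; ``forbid`` takes a list of
    category names.  Unknown keys raise.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    score_fields = {f.name for f in fields(ScoreSpec)}
    opt_fields = {f.name for f in fields(SearchOptions)}
    s_kw, o_kw = {}, {}
    for key, value in data.items():
        if key == "forbid":
            s_kw["forbid"] = frozenset(value or ())
        elif key in score_fields:
            s_kw[key] = value
        elif key in opt_fields:
            o_kw[key] = value
        else:
            raise ValueError(f"{path}: unknown config key {key!r}")
    return ScoreSpec(**s_kw), SearchOptions(**o_kw)
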