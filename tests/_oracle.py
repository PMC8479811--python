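"""Independent brute-force oracle for the MCS search.

Enumerates every connected, injective, bond-preserving partial atom mapping
between two topologies by naive recursive growth with deduplication, scores
each completed solution with a from-scratch re-implementation of the
penalty semantics (dummies, atom-level mismatches, bonded-term comparison,
both dihedral-matching procedures), and reports the best score and the set
of best mappings.  It shares nothing with the engine except the public
ring-policy validator used as a solution filter.
"""

from __future__ import annotations

import math
from itertools import combinations

from pertbuild import (AtomMatch, MatchSolution, SearchOptions, ScoreSpec,
                       enforce_ring_policy, perceive_rings, build_graph)
from pertbuild.core import DUMMY

INF = math.inf


def _adj(top):
    adj = {i: set() for i in range(len(top))}
    for i, j, _ in top.bonds:
        adj[i].add(j)
        adj[j].add(i)
    return adj


def connected_mappings(top_a, top_b):
    """All connected injective bond-preserving mappings A -> B (incl. {})."""
    adj_a, adj_b = _adj(top_a), _adj(top_b)
    seen = set()
    out = []

    def rec(mapping: dict):
        key = frozenset(mapping.items())
        if key in seen:
            return
        seen.add(key)
        out.append(dict(mapping))
        dom = set(mapping)
        cands = sorted(set().union(*(adj_a[a] for a in dom)) - dom) if dom \
            else range(len(top_a))
        used = set(mapping.values())
        for a in cands:
            for b in range(len(top_b)):
                if b in used:
                    continue
                ok = all((x in adj_a[a]) == (mapping[x] in adj_b[b])
                         for x in dom)
                if ok:
                    mapping[a] = b
                    rec(mapping)
                    del mapping[a]

    rec({})
    return out


def _close(p, q):
    return len(p) == len(q) and all(
        (int(a) == int(b)) if isinstance(a, int) or isinstance(b, int)
        else math.isclose(a, b, rel_tol=1e-9, abs_tol=1e-300)
        for a, b in zip(p, q))


def _term_dict(top, terms, canon):
    out = {}
    for t in terms:
        out.setdefault(canon(t[:-1]), []).append(top.resolve(t[-1]))
    return out


def score_mapping(top_a, top_b, mapping: dict,
                  spec: ScoreSpec, opts: SearchOptions):
    """Penalty key (dummies, weighted mismatch) of one mapping; None when
    the mapping is infeasible (created/removed bond, disallowed term
    creation or multiplicity change, forbidden category)."""
    counts = {c: 0 for c in ("atomtype", "mass", "charge", "bond", "angle",
                             "dihedral", "improper", "multiplicity")}
    dummies = (len(top_a) - len(mapping)) + (len(top_b) - len(mapping))
    for a, b in mapping.items():
        xa, xb = top_a.atoms[a], top_b.atoms[b]
        counts["atomtype"] += xa.type_id != xb.type_id
        counts["mass"] += abs(xa.mass - xb.mass) > 1e-6
        counts["charge"] += abs(xa.charge - xb.charge) > 1e-6

    inv = {v: k for k, v in mapping.items()}

    def mapped(idxs):
        return tuple(mapping[i] for i in idxs)

    # bonds: existence already preserved by construction; compare params
    bond_b = _term_dict(top_b, top_b.bonds, lambda t: frozenset(t))
    for i, j, ref in top_a.bonds:
        if i in mapping and j in mapping:
            pb_ = bond_b[frozenset(mapped((i, j)))]
            if not _close(top_a.resolve(ref), pb_[0]):
                counts["bond"] += 1

    feasible = True

    def compare_existence(dict_a, dict_b, category):
        nonlocal feasible
        keys = set(dict_a) | set(dict_b)
        for k in keys:
            pa, pb_ = dict_a.get(k), dict_b.get(k)
            if pa is None or pb_ is None:
                counts[category] += 1
                if not opts.allow_make_break_bonded:
                    feasible = False
            elif not _close(pa, pb_):
                counts[category] += 1

    def canon3(t):
        return min(t, t[::-1])

    ang_a = {canon3(mapped(t[:3])): top_a.resolve(t[3])
             for t in top_a.angles if all(i in mapping for i in t[:3])}
    ang_b = {canon3(t[:3]): top_b.resolve(t[3])
             for t in top_b.angles if all(i in inv for i in t[:3])}
    compare_existence(ang_a, ang_b, "angle")

    imp_a = {tuple(sorted(mapped(t[:4]))): top_a.resolve(t[4])
             for t in top_a.impropers if all(i in mapping for i in t[:4])}
    imp_b = {tuple(sorted(t[:4])): top_b.resolve(t[4])
             for t in top_b.impropers if all(i in inv for i in t[:4])}
    compare_existence(imp_a, imp_b, "improper")

    # dihedrals
    def canon4(t):
        return min(t, t[::-1])

    if opts.dihedral_match == "all_four_atoms":
        dih_a = _term_dict(top_a, [t for t in top_a.dihedrals
                                   if all(i in mapping for i in t[:4])],
                           lambda x: canon4(mapped(x)))
        dih_b = _term_dict(top_b, [t for t in top_b.dihedrals
                                   if all(i in inv for i in t[:4])],
                           lambda x: canon4(tuple(x)))
    else:
        dih_a = _term_dict(top_a, [t for t in top_a.dihedrals
                                   if all(i in mapping for i in t[:4])],
                           lambda x: tuple(sorted(mapped(x[1:3]))))
        dih_b = _term_dict(top_b, [t for t in top_b.dihedrals
                                   if all(i in inv for i in t[:4])],
                           lambda x: tuple(sorted(x[1:3])))
    for k in set(dih_a) | set(dih_b):
        la = sorted(dih_a.get(k, []), key=lambda p: (p[2], p[0], p[1]))
        lb = sorted(dih_b.get(k, []), key=lambda p: (p[2], p[0], p[1]))
        if len(la) != len(lb):
            counts["dihedral"] += 1
            if not opts.allow_make_break_bonded:
                feasible = False
            continue
        for pa, pb_ in zip(la, lb):
            if pa[2] != pb_[2]:
                counts["multiplicity"] += 1
                if (opts.dihedral_match == "all_four_atoms"
                        and not opts.allow_multiplicity_change):
                    feasible = False
            if not _close(pa[:2], pb_[:2]):
                counts["dihedral"] += 1

    if not feasible or any(counts[c] for c in spec.forbid if c in counts):
        return None
    if "dummy" in spec.forbid and dummies:
        return None
    mismatch = sum(counts[c] * spec.weight(c) for c in counts)
    return (float(dummies), mismatch)


def solution_from_mapping(top_a, top_b, mapping, opts):
    matches = [AtomMatch((a, b)) for a, b in sorted(mapping.items())]
    return MatchSolution([top_a, top_b], matches, opts).completed()


def best_by_brute_force(top_a, top_b, spec=None, opts=None):
    """(best score key, set of best mappings as frozensets of (a, b))."""
    spec = spec or ScoreSpec()
    opts = opts or SearchOptions()
    rings = [perceive_rings(build_graph(t), opts.ring_size_cap)
             for t in (top_a, top_b)]
    best_key, best_maps = None, set()
    for mapping in connected_mappings(top_a, top_b):
        key = score_mapping(top_a, top_b, mapping, spec, opts)
        if key is None:
            continue
        if any(rings):
            sol = solution_from_mapping(top_a, top_b, mapping, opts)
            if not enforce_ring_policy(sol, rings, opts):
                continue
        if best_key is None or key < best_key:
            best_key, best_maps = key, {frozenset(mapping.items())}
        elif key == best_key:
            best_maps.add(frozenset(mapping.items()))
    return best_key, best_maps
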