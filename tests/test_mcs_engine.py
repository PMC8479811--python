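"""MCS search engine: seeding, candidate expansion, policies, oracle
equivalence, pruning soundness, determinism."""

import numpy as np
import pytest

import pertbuild as pb
from pertbuild import fixtures as fx
from pertbuild.mcs_engine import SearchBudgetExceeded, _Engine
from pertbuild.molgraph import build_graph, perceive_rings
from _oracle import best_by_brute_force


def _engine_best(ta, tb, spec=None, opts=None):
    from dataclasses import replace
    opts = replace(opts or pb.SearchOptions(), enumerate_all_best=True,
                   max_solutions=100000)
    sols = pb.search([ta, tb], opts, spec or pb.ScoreSpec())
    return ((sols[0].score.key if sols else None),
            {frozenset(s.pair_mapping().items()) for s in sols})


class TestInitialPairs:
    def test_n_times_m(self, toy_pair):
        meth, eth = toy_pair
        assert len(pb.initial_pairs([meth, eth])) == 6  # 3 x 2

    def test_identical_four_atom_molecules(self):
        rng = np.random.default_rng(0)
        t = fx.random_topology(rng, 4)
        assert len(pb.initial_pairs([t, t])) == 16

    def test_single_state_rejected(self, toy_pair):
        with pytest.raises(pb.TopologyError):
            pb.initial_pairs([toy_pair[0]])


class TestExpandCandidates:
    def test_frontier_after_methyls_matched(self, toy_pair):
        """With the methyls matched, the next pivot is the oxygen: its
        candidates are (O, CH3) and (O, DUMMY); the hydrogen waits."""
        meth, eth = toy_pair
        sol = pb.MatchSolution([meth, eth], [pb.AtomMatch((0, 0))])
        cands = pb.expand_candidates(sol)
        assert {c.entries for c in cands} == {(1, 1), (1, None)}

    def test_complete_solution_has_no_candidates(self, toy_pair):
        meth, eth = toy_pair
        sol = pb.MatchSolution([meth, eth], [
            pb.AtomMatch((0, 0)), pb.AtomMatch((1, 1)),
            pb.AtomMatch((2, None))])
        assert pb.expand_candidates(sol) == []

    def test_ring_nonring_none_excludes_candidate(self):
        ring, _ = fx.make_fixture("cyclohexane")
        chain, _ = fx.make_fixture("hexane")
        opts = pb.SearchOptions(ring_nonring_policy="none")
        sol = pb.MatchSolution([ring, chain], [], opts)
        cands = pb.expand_candidates(sol, opts)
        assert all(c.entries[1] is None for c in cands)


class TestAddMatch:
    def test_identity_pair_adds_no_perturbation(self, toy_pair):
        meth, _ = toy_pair
        sol = pb.MatchSolution([meth, meth], [pb.AtomMatch((0, 0))])
        new = pb.add_match(sol, pb.AtomMatch((1, 1)))
        assert new.classify().counts.total() == 0

    def test_oxygen_onto_methyl_perturbs(self, toy_pair):
        meth, eth = toy_pair
        sol = pb.MatchSolution([meth, eth], [pb.AtomMatch((0, 0))])
        new = pb.add_match(sol, pb.AtomMatch((1, 1)))
        counts = new.classify().counts
        assert counts["atomtype"] >= 1 and counts["mass"] >= 1
        assert counts["charge"] >= 1 and counts["bond"] >= 1

    def test_bond_creating_match_rejected(self):
        """Pairing atoms bonded in one state but not the other violates
        bond preservation."""
        lys, _ = fx.make_fixture("lysine_side")
        eth, _ = fx.make_fixture("ethane_ua")
        sol = pb.MatchSolution([lys, eth], [pb.AtomMatch((0, 0))])
        with pytest.raises(pb.TopologyError):
            pb.add_match(sol, pb.AtomMatch((2, 1)))  # CD not bonded to CB


class TestSearchScenarios:
    def test_methanol_ethane_best_mapping(self, toy_pair):
        meth, eth = toy_pair
        sols = pb.search([meth, eth])
        mappings = {frozenset(s.pair_mapping().items()) for s in sols}
        assert frozenset({(0, 0), (1, 1)}) in mappings
        for s in sols:
            assert s.score.breakdown["dummy"] == 1  # H -> dummy

    def test_lysine_methylation_six_solutions(self, lysine_pair):
        lys, k3c = lysine_pair
        sols = pb.search([lys, k3c], pb.SearchOptions(enumerate_all_best=True))
        assert len(sols) == 6
        for s in sols:
            m = s.pair_mapping()
            assert {m[i] for i in (5, 6, 7)} == {5, 6, 7}  # H's onto methyls
            assert s.score.breakdown["dummy"] == 0

    def test_lysine_methylation_forbid_bond(self, lysine_pair):
        """Excluding perturbed bonds: hydrogens into dummies, methyls grown
        from dummies, the rest matched."""
        lys, k3c = lysine_pair
        spec = pb.ScoreSpec(forbid=frozenset({"bond"}))
        sols = pb.search([lys, k3c], pb.SearchOptions(enumerate_all_best=True),
                         spec)
        assert len(sols) == 1
        m = sols[0].pair_mapping()
        assert m == {i: i for i in range(5)}  # chain + N matched
        assert sols[0].score.breakdown["dummy"] == 6

    def test_acetylation_default_and_permissive_paths(self, acetyl_pair):
        lys, kac = acetyl_pair
        strict = pb.search([lys, kac])[0]
        assert strict.score.breakdown["dummy"] == 5
        assert 6 not in {b for a, b in strict.pair_mapping().items()}
        permissive = pb.search([lys, kac], pb.SearchOptions(
            allow_make_break_bonded=True,
            dihedral_match="middle_two_atoms"))[0]
        assert permissive.score.breakdown["dummy"] == 3
        assert 6 in permissive.pair_mapping().values()  # acetyl C matched
        # the all-four-atoms route needs the multiplicity permission too
        permissive2 = pb.search([lys, kac], pb.SearchOptions(
            allow_make_break_bonded=True, allow_multiplicity_change=True))[0]
        assert permissive2.score.key == permissive.score.key

    def test_self_match_every_fixture(self, named):
        for name, (top, _) in named.items():
            sols = pb.search([top, top], pb.SearchOptions(enumerate_all_best=False))
            assert sols[0].score.total == 0, name
            assert sols[0].score.breakdown.get("dummy", 0) == 0, name


class TestRingPolicies:
    def test_fused_partial_ring_match(self):
        dec, _ = fx.make_fixture("fused_bicycle")
        chx, _ = fx.make_fixture("cyclohexane")
        sol = pb.search([dec, chx], pb.SearchOptions(enumerate_all_best=False))[0]
        assert sol.n_matched_atoms == 6  # one complete ring

    def test_complete_only_blocks_partial_polycycle(self):
        dec, _ = fx.make_fixture("fused_bicycle")
        chx, _ = fx.make_fixture("cyclohexane")
        sol = pb.search([dec, chx], pb.SearchOptions(
            ring_policy="complete_only", enumerate_all_best=False))[0]
        assert sol.n_matched_atoms == 0

    def test_spiro_rings_are_independent(self):
        spiro, _ = fx.make_fixture("spiro_bicycle")
        cp, _ = fx.make_fixture("cyclopentane")
        sol = pb.search([cp, spiro], pb.SearchOptions(
            ring_policy="complete_only", enumerate_all_best=False))[0]
        assert sol.n_matched_atoms == 5  # one spiro ring fully matched

    @pytest.mark.parametrize("policy, expected", [
        ("two_bonded_atoms", 2), ("one_atom", 1), ("none", 0)])
    def test_ring_nonring_budgets(self, policy, expected):
        ring, _ = fx.make_fixture("cyclohexane")
        chain, _ = fx.make_fixture("hexane")
        sol = pb.search([ring, chain], pb.SearchOptions(
            ring_nonring_policy=policy, enumerate_all_best=False))[0]
        assert sol.n_matched_atoms == expected

    def test_returned_solutions_pass_independent_validation(self):
        """Post hoc: every returned solution obeys the ring policy and bond
        preservation (revalidated from scratch)."""
        for a, b, opts in [
                ("fused_bicycle", "cyclohexane", pb.SearchOptions()),
                ("cyclohexane", "hexane", pb.SearchOptions()),
                ("cyclohexane", "bridged_bicycle", pb.SearchOptions()),
        ]:
            ta, _ = fx.make_fixture(a)
            tb, _ = fx.make_fixture(b)
            rings = [perceive_rings(build_graph(t)) for t in (ta, tb)]
            for s in pb.search([ta, tb], opts):
                rebuilt = pb.MatchSolution([ta, tb], s.matches, opts)  # revalidates
                assert pb.enforce_ring_policy(rebuilt, rings, opts)


class TestDihedralMatching:
    def test_identical_molecules_all_matched(self, named):
        lys = named["lysine_side"][0]
        for mode in ("all_four_atoms", "middle_two_atoms"):
            opts = pb.SearchOptions(dihedral_match=mode)
            sol = pb.search([lys, lys], opts)[0]
            report = pb.match_dihedrals(sol, opts)
            assert report["perturbed"] == [] and report["created_removed"] == []
            assert len(report["matched"]) == 5

    def test_acetylation_dihedral_classification(self, acetyl_pair):
        lys, kac = acetyl_pair
        opts = pb.SearchOptions(allow_make_break_bonded=True,
                                dihedral_match="middle_two_atoms")
        sol = pb.search([lys, kac], opts)[0]
        report = pb.match_dihedrals(sol, opts)
        cats = {k: len(v) for k, v in report.items()}
        assert cats["multiplicity"] == 1  # amine -> amide rotamer term


class TestOracleEquivalence:
    NAMED_PAIRS = [
        ("methanol_ua", "ethane_ua"),
        ("lysine_side", "trimethyllysine_side"),
        ("lysine_side", "acetyllysine_side"),
        ("trimethyllysine_side", "acetyllysine_side"),
        ("cyclohexane", "hexane"),
        ("cyclohexane", "methylcyclohexane"),
        ("cyclohexane", "fused_bicycle"),
        ("cyclohexane", "bridged_bicycle"),
        ("cyclopentane", "spiro_bicycle"),
        ("ligand_h", "ligand_f"),
        ("methylcyclohexane", "dimethylcyclohexane_12"),
    ]

    @pytest.mark.parametrize("a, b", NAMED_PAIRS)
    def test_named_pairs(self, a, b, named):
        ta, tb = named[a][0], named[b][0]
        okey, omaps = best_by_brute_force(ta, tb)
        ekey, emaps = _engine_best(ta, tb)
        assert ekey == okey and emaps == omaps

    @pytest.mark.parametrize("spec, opts", [
        (pb.ScoreSpec(forbid=frozenset({"bond"})), None),
        (pb.eds_score_spec(), None),
        (None, pb.SearchOptions(allow_make_break_bonded=True,
                                dihedral_match="middle_two_atoms")),
        (None, pb.SearchOptions(ring_policy="complete_only")),
    ])
    def test_option_variants_on_lysine_and_rings(self, spec, opts, named):
        for a, b in [("lysine_side", "acetyllysine_side"),
                     ("cyclohexane", "fused_bicycle")]:
            ta, tb = named[a][0], named[b][0]
            okey, omaps = best_by_brute_force(ta, tb, spec, opts)
            ekey, emaps = _engine_best(ta, tb, spec, opts)
            assert ekey == okey and emaps == omaps

    def test_fifty_random_graph_pairs(self):
        rng = np.random.default_rng(20250925)
        for _ in range(50):
            ta = fx.random_topology(rng, int(rng.integers(4, 8)))
            tb = fx.random_topology(rng, int(rng.integers(4, 8)))
            okey, omaps = best_by_brute_force(ta, tb)
            ekey, emaps = _engine_best(ta, tb)
            assert ekey == okey and emaps == omaps


class TestSearchMechanics:
    def test_symmetry_of_arguments(self, lysine_pair):
        lys, k3c = lysine_pair
        k1, m1 = _engine_best(lys, k3c)
        k2, m2 = _engine_best(k3c, lys)
        assert k1 == k2
        assert m1 == {frozenset((b, a) for a, b in m) for m in m2}

    def test_pruning_never_changes_best_score(self, named):
        pairs = [("methanol_ua", "ethane_ua"),
                 ("lysine_side", "trimethyllysine_side"),
                 ("lysine_side", "acetyllysine_side"),
                 ("cyclohexane", "hexane"),
                 ("cyclohexane", "methylcyclohexane"),
                 ("ligand_h", "ligand_f")]
        for a, b in pairs:
            ta, tb = named[a][0], named[b][0]
            k1, m1 = _engine_best(ta, tb, opts=pb.SearchOptions(prune=True))
            k2, m2 = _engine_best(ta, tb, opts=pb.SearchOptions(prune=False))
            assert k1 == k2 and m1 == m2, (a, b)

    def test_determinism_of_repeated_runs(self, lysine_pair):
        lys, k3c = lysine_pair
        runs = [pb.search([lys, k3c], pb.SearchOptions(enumerate_all_best=True))
                for _ in range(2)]
        lists = [[tuple(m.entries for m in s.matches) for s in r] for r in runs]
        assert lists[0] == lists[1]

    def test_empty_state_rejected(self, toy_pair):
        with pytest.raises(pb.TopologyError):
            pb.search([toy_pair[0], pb.ForceFieldTopology("x", [])])

    def test_node_budget_aborts_with_diagnostic(self, lysine_pair):
        lys, k3c = lysine_pair
        with pytest.raises(SearchBudgetExceeded):
            pb.search([lys, k3c], pb.SearchOptions(max_nodes=5))
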