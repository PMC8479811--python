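"""Union perturbation topologies, dummy audits, perturbation file I/O."""

import pytest

import pertbuild as pb
from pertbuild import fixtures as fx
from pertbuild.core import SerializationError


def _pert(a, b, opts=None, spec=None, coords=None):
    ta, ca = fx.make_fixture(a)
    tb, cb = fx.make_fixture(b)
    sols = pb.search([ta, tb], opts or pb.SearchOptions(), spec or pb.ScoreSpec())
    best = pb.select_best(sols, [ca, cb] if (ca is not None and cb is not None)
                          else None, spec or pb.ScoreSpec())
    return ta, tb, pb.build_pert_topology(best)


class TestBuildPertTopology:
    def test_methanol_to_ethane_union(self):
        meth, eth, pert = _pert("methanol_ua", "ethane_ua")
        assert len(pert.atoms) == 3  # CH3, O/CH3, H(dummy in B)
        h = pert.atoms[2]
        assert not h.per_state[0].is_dummy and h.per_state[1].is_dummy
        assert h.per_state[1].type_id == "DUM"
        assert h.per_state[1].charge == 0.0

    def test_forbid_bond_dummy_pattern(self):
        spec = pb.ScoreSpec(forbid=frozenset({"bond"}))
        _, _, pert = _pert("lysine_side", "trimethyllysine_side", spec=spec)
        dummies_b = [ua for ua in pert.atoms if ua.per_state[1].is_dummy]
        dummies_a = [ua for ua in pert.atoms if ua.per_state[0].is_dummy]
        assert len(dummies_b) == 3 and len(dummies_a) == 3
        names_b = {ua.per_state[0].name for ua in dummies_b}
        assert names_b == {"H1", "H2", "H3"}

    def test_identity_perturbation_is_clean(self):
        _, _, pert = _pert("lysine_side", "lysine_side")
        assert all(not ua.is_perturbed for ua in pert.atoms)
        assert all(not ua.dummy_states for ua in pert.atoms)

    def test_incomplete_solution_rejected(self):
        meth, _ = fx.make_fixture("methanol_ua")
        eth, _ = fx.make_fixture("ethane_ua")
        sol = pb.MatchSolution([meth, eth], [pb.AtomMatch((0, 0))])
        with pytest.raises(pb.TopologyError):
            pb.build_pert_topology(sol)

    @pytest.mark.parametrize("a, b", [
        ("methanol_ua", "ethane_ua"),
        ("lysine_side", "trimethyllysine_side"),
        ("lysine_side", "acetyllysine_side"),
        ("cyclohexane", "fused_bicycle"),
        ("ligand_h", "ligand_f"),
    ])
    def test_state_restriction_reproduces_inputs(self, a, b):
        ta, tb, pert = _pert(a, b)
        assert pb.semantically_equal(pb.restrict_to_state(pert, 0), ta)
        assert pb.semantically_equal(pb.restrict_to_state(pert, 1), tb)

    def test_dummy_neutrality(self):
        """State charges sum to the input totals; dummies contribute zero."""
        ta, tb, pert = _pert("lysine_side", "trimethyllysine_side")
        for k, top in enumerate((ta, tb)):
            total = sum(ua.per_state[k].charge for ua in pert.atoms)
            assert abs(total - top.total_charge()) < 1e-9

    def test_dummy_exclusions_copied_from_real_state(self):
        _, _, pert = _pert("methanol_ua", "ethane_ua")
        h = pert.atoms[2]
        # H keeps its exclusions in the state where it is a dummy
        exc_a = {j for i, js in pert.exclusions[0].items()
                 for j in js if i == h.index} | \
                {i for i, js in pert.exclusions[0].items() if h.index in js}
        exc_b = {j for i, js in pert.exclusions[1].items()
                 for j in js if i == h.index} | \
                {i for i, js in pert.exclusions[1].items() if h.index in js}
        assert exc_a and exc_a <= exc_b


class TestDummyAudit:
    def _audit(self, opts=None):
        _, _, pert = _pert("lysine_side", "acetyllysine_side", opts)
        return pb.audit_dummies(pert), pert

    def test_acetyl_carbon_five_interactions_two_redundant(self):
        """Under the restrictive options the acetyl carbon becomes a dummy
        with one bond, two angles, one proper and one improper dihedral to
        the unperturbed atoms — two redundant terms, warning raised."""
        audit, pert = self._audit()
        rep = {r.name: r for r in audit.reports}
        c = rep["CH"]
        assert c.n_anchor_terms == 5 and c.redundant == 2 and c.warning
        assert c.by_kind == {"bond": 1, "angle": 2, "dihedral": 1, "improper": 1}
        assert audit.has_warnings

    def test_well_anchored_dummies_silent(self):
        audit, _ = self._audit()
        rep = {r.name: r for r in audit.reports}
        for h in ("H2", "H3"):
            assert rep[h].n_anchor_terms == 3 and not rep[h].warning

    def test_permissive_route_is_silent(self):
        """The alternative acetylation pathway anchors every dummy by
        exactly three nonredundant terms."""
        audit, _ = self._audit(pb.SearchOptions(
            allow_make_break_bonded=True, dihedral_match="middle_two_atoms"))
        assert not audit.has_warnings
        assert all(r.n_anchor_terms in (0, 3) for r in audit.reports)

    def test_single_bond_anchor_warns_under_anchored(self):
        meth, eth, pert = _pert("methanol_ua", "ethane_ua")
        audit = pb.audit_dummies(pert)
        (h,) = audit.reports
        assert h.by_kind["bond"] == 1 and h.under_anchored and h.warning


class TestPerturbationFiles:
    @pytest.mark.parametrize("dialect", ["gromacs", "gromos"])
    def test_round_trip(self, tmp_path, dialect):
        for a, b in [("methanol_ua", "ethane_ua"),
                     ("lysine_side", "acetyllysine_side")]:
            _, _, pert = _pert(a, b)
            prefix = tmp_path / f"{a}_{b}_{dialect}"
            pb.write_perturbation(pert, prefix, dialect)
            back = pb.read_perturbation(prefix, dialect)
            assert pb.pert_equal(pert, back), (a, b, dialect)

    def test_gromacs_atoms_carry_b_state_columns(self, tmp_path):
        _, _, pert = _pert("methanol_ua", "ethane_ua")
        pb.write_perturbation(pert, tmp_path / "p", "gromacs")
        text = (tmp_path / "p.top").read_text()
        h_line = next(l for l in text.splitlines() if l.startswith("3 "))
        assert "DUM" in h_line and h_line.split()[9] == "0.000000"

    def test_identity_perturbation_columns_equal(self, tmp_path):
        _, _, pert = _pert("ethane_ua", "ethane_ua")
        pb.write_perturbation(pert, tmp_path / "i", "gromacs")
        for line in (tmp_path / "i.top").read_text().splitlines():
            tok = line.split()
            if len(tok) == 11 and tok[0].isdigit():
                assert tok[1] == tok[8] and tok[6] == tok[9] and tok[7] == tok[10]

    def test_multistate_pert_needs_eds_writer(self, tmp_path):
        lys, _ = fx.make_fixture("lysine_side")
        k3c, _ = fx.make_fixture("trimethyllysine_side")
        kac, _ = fx.make_fixture("acetyllysine_side")
        sol = pb.multistate_search([lys, k3c, kac])
        eds = pb.build_eds_topology(sol)
        with pytest.raises(SerializationError):
            pb.write_perturbation(eds, tmp_path / "x", "gromacs")
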