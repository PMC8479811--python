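"""Lysine acetylation: two perturbation routes and the dummy-atom audit.

Under the default (restrictive) matching options, the acetyl group grows
entirely from dummy atoms; the acetyl carbon then carries five bonded
interactions with the unperturbed atoms (one bond, two angles, one proper
and one improper dihedral) — two more than the three nonredundant anchors
a dummy needs, so the audit warns.  Allowing the creation/removal of
non-bond bonded terms plus middle-two-atom dihedral matching instead
matches the carbon onto an amine hydrogen; every remaining dummy is then
anchored by exactly three terms and the audit is silent.  Redundant terms
are only reported, never removed automatically.
"""

import pertbuild as pb
from pertbuild import fixtures as fx

lysine, _ = fx.make_fixture("lysine_side")
acetyllysine, _ = fx.make_fixture("acetyllysine_side")

for label, opts in [
        ("restrictive (default)", pb.SearchOptions()),
        ("permissive (make/break + middle-two dihedrals)",
         pb.SearchOptions(allow_make_break_bonded=True,
                          dihedral_match="middle_two_atoms"))]:
    sol = pb.search([lysine, acetyllysine], opts)[0]
    pert = pb.build_pert_topology(sol)
    audit = pb.audit_dummies(pert)
    print(f"\n{label}: {sol.score.breakdown['dummy']} dummy matches")
    for r in audit.reports:
        print(f"  dummy {r.name}: {r.n_anchor_terms} anchoring term(s) "
              f"{dict(r.by_kind)}, {r.redundant} redundant")
    for msg in audit.warnings:
        print(f"  WARNING: {msg}")
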