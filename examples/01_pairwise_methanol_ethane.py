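"""Pairwise perturbation of the toy problem: methanol into ethane.

Builds the two united-atom molecules, runs the default MCS search, and
prints the best atom mapping with its penalty breakdown.  The expected
outcome: the two methyl particles match, the oxygen is matched onto the
second methyl (perturbing its type, mass, charge and the bond), and the
hydroxyl hydrogen is perturbed into a noninteracting dummy atom.
"""

import pertbuild as pb
from pertbuild import fixtures as fx

methanol, _ = fx.make_fixture("methanol_ua")
ethane, _ = fx.make_fixture("ethane_ua")

solutions = pb.search([methanol, ethane])
best = solutions[0]

print(f"best solutions found: {len(solutions)} (score {best.score.total})")
print(f"penalty breakdown: {dict(best.score.breakdown)}")
for m in best.matches:
    a = methanol.atoms[m[0]].name if m[0] is not None else "DUMMY"
    b = ethane.atoms[m[1]].name if m[1] is not None else "DUMMY"
    print(f"  {a:>6} <-> {b}")

pert = pb.build_pert_topology(best)
pb.write_perturbation(pert, "methanol_to_ethane", "gromacs")
print("wrote methanol_to_ethane.top (GROMACS dual-state columns)")
print("the dummy count (1) is the hydrogen that exists only in methanol;")
print("each nonzero breakdown entry is one force-field parameter that the")
print("alchemical transformation must interpolate.")
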