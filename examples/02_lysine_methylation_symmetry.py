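"""Lysine trimethylation: six symmetric solutions and the RMSD tie-break.

The default score maximizes matched atoms, so the three amine hydrogens
map onto the three united-atom methyls in every possible way: 3! = 6 best
solutions with identical scores.  Supplying coordinates ranks them by the
atom-positional RMSD over matched atoms (no fitting), which picks the
geometrically aligned assignment — the option meant for ligands posed in
a binding pocket.

A second search forbids bond perturbations: then the hydrogens are
perturbed into dummies and the methyls grown from dummies instead.
"""

import pertbuild as pb
from pertbuild import fixtures as fx

lysine, lys_xyz = fx.make_fixture("lysine_side")
k3c, k3c_xyz = fx.make_fixture("trimethyllysine_side")

solutions = pb.search([lysine, k3c], pb.SearchOptions(enumerate_all_best=True))
print(f"equal-score best solutions: {len(solutions)}")
for s in solutions:
    rmsd = pb.rmsd_of_mapping(s, [lys_xyz, k3c_xyz])
    hs = {lysine.atoms[a].name: k3c.atoms[b].name
          for a, b in s.pair_mapping().items() if lysine.atoms[a].name[0] == "H"}
    print(f"  {hs}  rmsd = {rmsd:.4f} nm")

best = pb.select_best(solutions, [lys_xyz, k3c_xyz])
print("selected (minimal RMSD):",
      {lysine.atoms[a].name: k3c.atoms[b].name
       for a, b in best.pair_mapping().items()})

spec = pb.ScoreSpec(forbid=frozenset({"bond"}))
alt = pb.search([lysine, k3c], spec=spec)[0]
print(f"\nwith perturbed bonds forbidden: {alt.score.breakdown['dummy']} dummy "
      "matches (hydrogens removed, methyls grown from dummies)")
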