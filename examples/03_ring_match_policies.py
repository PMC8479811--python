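"""Ring-matching policies on cycloalkane test systems.

Fused polycycles may match a monocycle ring-by-ring (partial ring match)
or only as a whole (complete-only).  Ring-to-nonring matches are limited
to two bonded atoms, one atom, or nothing — the matched-substructure size
shrinks accordingly.
"""

import pertbuild as pb
from pertbuild import fixtures as fx

decalin, _ = fx.make_fixture("fused_bicycle")
cyclohexane, _ = fx.make_fixture("cyclohexane")
hexane, _ = fx.make_fixture("hexane")

for policy in ("complete_individual_rings", "complete_only"):
    sol = pb.search([decalin, cyclohexane], pb.SearchOptions(
        ring_policy=policy, enumerate_all_best=False))[0]
    print(f"decalin vs cyclohexane, {policy}: "
          f"{sol.n_matched_atoms} matched atoms")
# 6 matched under the partial-ring policy (one complete ring), 0 under
# complete-only: a fused system cannot be matched in part.

for policy in ("two_bonded_atoms", "one_atom", "none"):
    sol = pb.search([cyclohexane, hexane], pb.SearchOptions(
        ring_nonring_policy=policy, enumerate_all_best=False))[0]
    print(f"cyclohexane vs hexane, ring-nonring {policy}: "
          f"{sol.n_matched_atoms} matched atoms")
# the allowed ring-to-chain overlap shrinks 2 -> 1 -> 0.
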