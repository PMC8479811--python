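# Methods

## Problem and model

A single-topology alchemical perturbation needs one merged atom set in
which every end state is embedded: matched atoms carry per-state
parameters, unmatched atoms become noninteracting dummies in the states
where they do not exist.  `pertbuild` poses the matching step as a
maximum-common-substructure (MCS) problem over force-field topologies —
the graph is the bond graph, and atom/term attributes are the force-field
parameters, not element chemistry.  Aromaticity and stereochemistry are
deliberately not perceived: what the simulation engine sees is the
topology, so the topology drives the matching.

### Solution space

A solution is a list of match tuples, one entry per state (atom index or
DUMMY; at least one entry real).  Constraints:

* injectivity — each real atom appears in at most one tuple;
* bond preservation — for two tuples both real in states *s*, *t*, a bond
  between their atoms exists in *s* iff it exists in *t*; bonds are never
  created or removed by a match;
* connected growth — the multi-real (matched) tuples form one connected
  region grown from first neighbors of the current solution;
* for multistate runs (N ≥ 3) additionally: a tuple may be bonded to a
  matched tuple only if that tuple is real and bonded in *all* of its own
  real states.  Without this rule, two tuples overlapping in a single
  shared state can chain peripheral atoms of different states into one
  "chimeric" union atom whose bonded neighborhood differs per state; such
  unions are never what a common scaffold means and their admission grows
  the search space explosively.  For N = 2 the rule coincides with plain
  bond preservation.

A solution is complete when every atom of every state is present, matched
to real atoms or explicitly to DUMMY; leftovers are auto-paired with
dummies at completion.

### Scoring

Categories counted on a solution: dummy entries; per-tuple atom-type,
mass and charge mismatches (number of distinct values − 1, with masses and
charges compared at 1e-6 absolute tolerance); perturbed or
created/removed bonds, angles, proper and improper dihedrals (resolved
numeric parameters compared at 1e-9 relative tolerance — identical physics
under different labels is not a perturbation); dihedral multiplicity
changes.  Terms reaching into a dummy branch (any participating atom
dummy-matched, or tuple not real in both compared states) are *dummy
region* terms: kept, never penalized.  The total is Σ count × weight.

Defaults: `w_dummy = 1000`, every mismatch weight 1.  With default-style
weights the comparison key is the exact lexicographic pair
`(dummy count, weighted mismatch)` rather than one float, so weight
magnitudes cannot produce rounding artifacts; a `custom_score` callable
replaces the key entirely.  Forbidden categories (and infeasible patterns:
a created/removed term without `allow_make_break_bonded`, a multiplicity
change without its flag) map to an infinite sentinel.

Dihedral pairing has two procedures.  `all_four_atoms` groups dihedrals by
the mapped atom quadruple; several dihedrals on one quadruple are paired
in sorted (multiplicity, phase, force-constant) order; a multiplicity
difference then requires `allow_multiplicity_change`.  `middle_two_atoms`
groups by the mapped central bond and treats multiplicity like any other
parameter difference.  That asymmetry is intentional: the two options must
be alternative routes to the same permissive outcome (an amine→amide
rotamer term can be matched either by explicitly allowing the multiplicity
change under four-atom pairing, or by pairing on the central bond), and it
is the only reading under which both routes produce the identical
solution, which the tests assert.  The first procedure suits topologies
that enumerate all dihedrals from connectivity, the second suits one
dihedral per rotatable bond.

### Search and pruning

The engine enumerates by depth-first branching on one pivot atom at a
time — the smallest unassigned atom adjacent to the matched region, or the
smallest unassigned atom overall until a two-state match exists.  Branches
assign the pivot to a compatible tuple or to DUMMY.  Because the pivot is
a deterministic function of the partial assignment, every assignment is
visited exactly once (no transposition duplicates), and output order is
deterministic.

Pruning uses an admissible lower bound.  The dummy component exploits an
identity: with T tuples in a complete N-state solution,
`#dummy entries = N·T − Σ_s n_s`, so bounding dummies reduces to bounding
the final tuple count from below: current tuples + one per atom
unreachable from the matched region (those can only become dummy
singletons) + the largest per-state count of reachable unassigned atoms
(atoms of one state never share a tuple).  Added to the accumulated
(monotone) mismatch penalty this never exceeds the score of any
completion, so pruning cannot discard an optimum; a dedicated test
compares pruned and unpruned runs, and an exhaustive brute-force oracle
(an independent implementation in the test suite) reproduces best scores
and best-mapping sets on all demonstration pairs and on 50 random
attributed molecules per run.

Candidate ordering inside the engine uses a cheap proxy (fewest new
dummies, then fewest atom-level mismatches, then canonical index order);
the public `expand_candidates` sorts by the exact lower bound.  The
ordering affects only how soon the incumbent is found, never the result.
Search cost is exponential in the worst case; a node-expansion budget
(default 2·10⁶) aborts with a diagnostic rather than running unbounded.

### Ring policies

Rings are perceived as a deterministic smallest-set-of-smallest-rings:
simple cycles up to 12 atoms (configurable; larger macrocycles are treated
as acyclic) sorted by size and lexicographic atom order, picked greedily
under GF(2) edge-space independence.  Ring pairs are classified fused
(exactly one shared edge), spiro (exactly one shared atom), bridged (two
or more shared atoms that are not one shared edge).

Policy enforcement, per ordered state pair: under
`complete_individual_rings` every matched ring atom must be covered by
some completely matched ring; uncovered matched ring atoms — whether their
partner is a ring atom or not — fall under the `ring_nonring_policy`
budget (two atoms sharing a bond / one atom / none).  Under
`complete_only`, a connected ring *system* (rings related by fusion or
bridging; spiro junctions start a new system) must be matched in its
entirety or carry no ring-to-ring match; a lone ring may still share its
spiro junction atom with a completely matched sibling.  Bridged pairs are
all-or-nothing under either policy.  The ring-to-nonring budget is
enforced incrementally during the search (such matches can never become
ring-covered later); the full policy is validated when a solution
completes.  How three or more mutually fused rings combine is not uniquely
defined by the pairwise rules; the implementation applies the per-ring
coverage rule with shared atoms counted once, which reduces to the
pairwise behavior on the fixtures.

### Coordinate ranking

`rmsd_of_mapping` computes the spread over match tuples real in every
state, **without** least-squares fitting — input poses (e.g. ligands in a
binding pocket) are information, and a fit would destroy it.  Pairwise:
plain RMSD over matched pairs.  Multistate: ⟨RMSD²⟩^1/2 over state pairs
or ⟨RMSF²⟩^1/2 about tuple centroids.  The identity
Σ_{i<j}|x_i−x_j|² = N·Σ_i|x_i−x̄|² gives ⟨RMSD²⟩ = 2N/(N−1)·⟨RMSF²⟩; the
constant was derived analytically and is verified numerically to 1e-10 in
the tests before being relied on.  `select_best` orders by score key, then
mapping RMSD (when coordinates are given), then a canonical tuple order,
so repeated runs select the same solution.

### Union topologies, dummies, audit

`build_pert_topology` merges two states of a complete solution: union
atoms ordered by state-A index then remaining state-B atoms; dummy-state
entries get the configurable noninteracting type (default `DUM`), zero
charge, and the real state's mass (mass interpolation of vanishing atoms
is avoided; the GROMOS multistate block could not express it anyway).
Angles/dihedrals/impropers confined to one state's dummy region keep that
state's parameters in both states, preserving the dummy branch's geometry.
Exclusions and 1-4 pairs are kept per state; dummy atoms inherit the
exclusions of their real-state atom.  Restricting a union topology to an
end state (dropping dummies and absent terms) reproduces the input
topology exactly — asserted field-by-field for every generated
perturbation and EDS topology.

The audit counts, for each dummy atom, the bonded terms whose other atoms
are all never-dummy ("anchors").  Three nonredundant anchors position a
dummy; `redundant = max(0, anchors − 3)` triggers a warning, as does an
under-anchored dummy (one or two anchors).  A dummy with zero anchors sits
inside a dummy branch and is positioned through its neighbors, so it is
not flagged.  Redundant terms are reported only — removal is not uniquely
defined and is left to the user.

### Multistate and EDS

The default multistate score forbids all bonded-term perturbations (atom
types, masses, charges may switch) — the construction of an EDS reference
topology.  `build_eds_topology` validates that constraint term-by-term;
`pairwise_from_multistate` projects one multistate mapping onto all
N(N−1)/2 state pairs, so cycle closure of the atom maps holds by
construction (and is asserted).  Multistate runs cost distinctly more than
pairwise ones; diverse compound libraries are out of scope and hit the
node budget.

## File formats

GROMOS11: TITLE / ATOMTYPENAME / SOLUTEATOM (exclusions and 1-4 lists on
the atom lines) / bonded type+term blocks, `END`-delimited, written
1-based.  GROMACS: `[ moleculetype ] / [ atoms ] / [ bonds ] / [ angles ]
/ [ dihedrals ] / [ pairs ] / [ exclusions ]` with inline parameters
(funct 1 bonds/angles/propers, funct 2 impropers), `#include` inlined
textually (unresolved includes are an error) and flat `#define` macros
substituted.  The same numeric parameter values are written in both
dialects; the fixture parameters are synthetic, internally consistent
constants, so no engine-specific functional-form conversion is performed.
Perturbation output: GROMACS dual-state columns (`typeB chargeB massB`,
A/B parameters on bonded lines; a multiplicity change is written with both
multiplicities); GROMOS reference topology plus
PERTATOMPARAM/PERTBONDSTRETCH/PERTBONDANGLE/PERTPROPERDIH/PERTIMPROPERDIH
blocks with numeric A- and B-state values, and an MPERTATOM-style block
(per-state type and charge) for EDS.  Soft-core parameters are simulation
input, not topology content, and are never written.  Atom names are
written from the first real state (the formats carry one name column);
per-state names live only in memory.  Created/removed terms are written
with a zero force constant in the state where they are absent.

## The fixture generator

Fixtures emulate the demonstration systems as united-atom molecules with
invented but fixed parameter constants: methanol/ethane; the lysine side
chain with trimethylated and acetylated forms; hexane, cyclo-pentane/
-hexane, methyl- and dimethylcyclohexanes; decalin-like fused,
bicyclo[2.2.2]octane-like bridged and spiro[4.4]nonane-like spiro
bicycles; an aromatic six-ring scaffold with H or F at one position.
Term lists are minimal but complete in the sense a careful united-atom
parameterization would be: rings carry all two-path angles; chains carry
one proper dihedral per central bond; the amine nitrogen carries one
N–H angle and one proper per hydrogen (no H–N–H angles), which keeps each
dummy hydrogen anchored by exactly three nonredundant terms; the amide
fixture defines the planarity impropers and both carbonyl-bond propers so
the two acetylation routes exhibit the characteristic term arithmetic of
an amide dummy branch (5 anchors, 2 redundant for the acetyl carbon;
silence on the permissive route).  Synthetic coordinates accompany the molecules used in RMSD
ranking, with the methyl positions slightly rotated from the hydrogen
positions so exactly one of the six symmetric solutions is geometrically
aligned.  `random_topology` draws uniform random labeled trees with random
types/charges and two parameter classes for bonds and angles — the shapes
the exhaustive oracle can score unambiguously.

What the fixtures do **not** emulate: real force-field parameter values,
conformational diversity, solvent, or molecules beyond ~10 atoms.  Passing
tests therefore demonstrate correctness of the matching/scoring/building
machinery, not force-field accuracy; on real topologies the same code
paths apply but runtimes grow with molecule size.

## Problem sizes and budgets

The default test suite and the acceptance script run pairwise searches on
2–10-atom molecules, a three-state search on the 8/8/9-atom lysine triple,
50 random 4–7-atom oracle pairs, and file round trips over all fixtures —
about half a minute end to end on one CPU.  These sizes were chosen so the
exhaustive oracle (exponential by nature) stays exact.

## Known limitations

* No stereochemistry or aromaticity; matching is purely graph + parameter
  based.
* The candidate-sort heuristic is a proxy for the stated
  "estimated number of additional matches"; it affects speed only.
* Ring policies beyond the demonstrated cases (three or more mutually
  fused rings, polycycle-to-polycycle sub-ring correspondences) follow the
  documented extrapolation of the pairwise rules.
* GROMOS EDS output cannot express per-state masses (serialization error
  by design); GROMACS EDS output is one topology file per state.
* Redundant dummy-anchoring terms are detected and reported, never
  removed.
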