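# Methods

## Problem and model

`ligpath` searches for full-atom ligand binding/unbinding pathways through a
protein.  A **pathway** is an ordered sequence of **frames**; each frame fixes
the ligand pose (centre-of-mass position, rigid orientation, torsion angles)
and the receptor state (global elastic-network deformation amplitudes,
side-chain rotamer choices near the ligand).  Candidate pathways are evolved
with the NSGA-II multi-objective genetic algorithm against up to three
minimised objectives, and the run returns the cumulative Pareto archive of
mutually non-dominated solutions.

## Genotype

* **Path gene.** Waypoints of the ligand COM.  Two geometric constraints
  apply: consecutive waypoints are at most `max_step` apart (by default
  `clamp(0.25 x ligand bounding-sphere radius, 0.5 A, 1.0 A)`; a recipe value
  overrides this), and the distance to the origin must grow by at least
  `min_increment` per frame (default 0.8 A).  Positive increments force
  outward progress and provably terminate on any bounded receptor; zero or
  negative values admit curved U/S-shaped routes at the cost of more frames.
  The frame count is therefore emergent, not fixed.  Three direction modes:
  *unbinding* (origin known; the walk stops when the COM leaves the receptor
  bounding sphere by 2 A and no receptor atom is within 5 A — an operational
  "bulk solvent reached" test), *binding* (destination known; starts seeded at
  the six points where the receptor's principal inertia axes pierce its
  bounding surface), and *two_point*.
* **Orientation gene.** A free rigid rotation per frame (unit quaternion).
  Disabled internally for single-atom ligands, where it is a no-op.
* **Torsion gene.** One angle per rotatable bond per frame.  A bond is
  rotatable when both endpoints are non-terminal heavy atoms, at least one is
  typed C3/N3/C2/N2/P by the connectivity-based typing, and the bond is not
  in a ring.  Rotations are applied to the smaller side of the bond and are
  relative (a zero gene is the identity).
* **Normal-mode gene.** Per-frame amplitudes (A, bounded at +/-3 by default)
  on the lowest non-rigid modes of an anisotropic network model built on the
  C-alpha trace (unit springs within a 15 A cutoff by default, 5 modes).  The
  3M x 3M Hessian is diagonalised exactly; the six-dimensional rigid-body
  null space is discarded.  All-atom extension is a rigid per-residue
  translation with the residue's C-alpha; no force-field relaxation follows,
  so large amplitudes can distort local geometry — the clash objective is
  what keeps them honest.
* **Rotamer gene.** One library index per rotamer-capable residue per frame
  (-1 keeps the native side chain).  Only residues with an atom within 5 A of
  the ligand at that frame are actually rebuilt, so the mutable set is
  recomputed per frame; choices are independent between frames.  The packaged
  table is a compact backbone-independent reduction (three most-probable
  rotamers per residue type with canonical gauche/trans chi values and
  representative probabilities); GLY/ALA/PRO are never resampled.  Side
  chains are rebuilt by measuring the current chi and rotating the distal
  atoms to the target, which preserves backbone coordinates exactly.

## Objectives

All objectives are minimised per frame and aggregated over frames by average
or maximum (per objective, user-chosen).  Average suits campaigns where all
solutions share a shape (e.g. a channel crossing); maximum resists the
dilution of one terrible frame by many good ones.

* **Clashes (A^3).** Summed pairwise van-der-Waals sphere intersection
  volumes (exact two-sphere lens closed form; Bondi radii).  Reference atoms
  are the ligand atoms plus the beta carbons of mutated rotamer residues; the
  evaluation zone is every atom within 5 A of a reference atom.  Contributing
  pairs: ligand-receptor, mutated-side-chain vs zone (excluding same-residue
  pairs, whose geometry is library-built), and intra-ligand pairs three or
  more bonds apart.  1-2 and 1-3 pairs are excluded; hydrogens are ignored,
  keeping the objective consistent with the heavy-atom energy term.
* **Vina-form energy (kcal/mol).** The published AutoDock Vina functional
  form — gauss1, gauss2, repulsion, hydrophobic and hbond terms on the
  surface distance `d = r - R1 - R2` with the published weights and an 8 A
  cutoff — restricted to intermolecular heavy-atom pairs, with no rotor
  penalty.  Implemented natively for testability rather than shelling out to
  a docking binary.  Because it sees no intramolecular repulsion it must be
  combined with the clash objective (the recipe validator enforces this).
  Donor/acceptor typing needs explicit hydrogens; a molecule containing N or
  O but no H is rejected at typing time (not at file-read time, so that
  hydrogen-free pseudo-atom fixtures still parse).
* **Smoothness (A).** `max(0, RMSD - cutoff)` between consecutive ligand
  conformations on raw coordinates, cutoff 1.0 A by default.  No
  superposition is performed: a rigid end-over-end flip between frames is
  exactly the pathology this objective exists to penalise, and fitting would
  erase it.

## Search

Standard NSGA-II: fast non-dominated sorting, crowding distance (a
zero-range objective contributes zero, avoiding 0/0), binary tournaments on
(rank, crowding), elitist environmental selection from parents plus
offspring.  Defaults: population 12; generations 500/750/1000 for 1/2/3
objectives; per offspring, crossover with probability 0.2, else mutation
with probability 0.8, else a copy.  Rank-1 individuals feed a cumulative
archive that is kept mutually non-dominated; a failed evaluation gets
worst-case scores and a warning rather than aborting the run.  Runs are
bit-reproducible from (recipe, seed).

Two engine choices were genuinely open and are worth recording:

* **Ties prefer newer individuals.**  Environmental selection breaks exact
  (rank, crowding) ties toward the most recently created individual.  With
  ties toward parents, offspring that match but do not beat their parent are
  always discarded, and the population cannot drift across score plateaus —
  on constricted channels this froze the search visibly.  Newer-first keeps
  selection deterministic and restores neutral drift.
* **Clash-guided local mutation.**  The path mutation is a mixture: local
  jitter of single waypoints (60%), tail resampling from a random index
  (30%), and full path reseeding (10%).  Evaluation annotates the genome
  with its per-frame clash profile, and the jitter picks its waypoint with
  probability proportional to that profile (falling back to uniform 30% of
  the time and whenever no annotation exists).  A maximum-aggregated clash
  objective is decided by a handful of bottleneck frames; unguided jitter
  almost never touches them, while guided jitter polishes exactly the
  waypoints that matter.  Continuous genes use Gaussian perturbation
  (sigma 30 degrees for torsions, 10% of the bound for amplitudes) and blend
  crossover; rotamer choices are uniformly resampled and uniformly swapped.

## Refinement

Discrete frames can still hide an inter-frame bottleneck.  `refine_pathway`
checks every consecutive pair by dense interpolation in rigid-pose space
(linear COM, quaternion slerp; torsions frozen at the endpoint
interpolation) and bridges violating pairs with RRT-Connect: two trees grown
from the endpoint poses, greedy connect extensions, goal bias 0.2, pose
metric = COM distance + 1 A/rad quaternion geodesic.  Collision means frame
clash at or above a threshold (default 50 A^3, matching the analysis filter
used to shortlist solutions).  Inserted frames take the earlier frame's
receptor state and carry recomputed clash scores; original frames are never
removed or reordered, and an unsolvable pair is annotated as a gap rather
than silently dropped.

## Synthetic study systems

Real channel systems need structure downloads and multi-hour campaigns, so
the shipped fixtures are analytic stand-ins with known answers:

* **Tube receptors** — hollow cylinders of carbon pseudo-atoms (2 A wall
  spacing), each atom named CA (so the whole wall is the elastic network)
  and owning its own residue.  `inner_radius` is the free lumen radius; an
  optional bottleneck ring constricts it.  A 1.7 A probe atom through a
  1.5 A bottleneck must accept some overlap (wall centres at 3.2 A < 3.4 A
  contact distance) while a 2.5 A bottleneck is passable at zero clash —
  which is exactly the ordering the tube comparison tests exploit.
* **Toy ligands** — a single carbon; all-trans alkane-like chains (n heavy
  atoms, n-3 rotatable bonds under the typing rule, explicit hydrogens); a
  glycerol-like branched triol.
* **Tripeptide** — a synthetic ALA-VAL-ALA built from standard internal
  coordinates (NeRF construction) for rotamer tests; it is an idealized
  stand-in, not a crystallographic fragment.

What the fixtures do **not** emulate: real packing heterogeneity, backbone
chemistry in the walls (no H-bond donors/acceptors in a carbon tube),
protonation, solvent, or the conformational coupling a force field would
impose.  Passing tests on them therefore demonstrate the correctness of the
geometry, scoring and search machinery, not predictive accuracy on real
proteins — for that, the tool must be run on prepared PDB-derived mol2/PDB
inputs (separate receptor/ligand files with explicit hydrogens).

## Numerical choices and degenerate inputs

* Sphere-overlap: exact lens formula; full containment returns the smaller
  sphere's volume; tangency and beyond return 0.
* The increment/step feasibility check rejects `min_increment > max_step`
  outright (no step can satisfy both).  Walk sampling is rejection-based with
  a radially-outward fallback that always satisfies a feasible constraint
  pair.
* ANM requires at least 3 C-alphas and a connected contact graph (a
  disconnected network at the chosen cutoff raises with advice to enlarge
  it).  Eigenvalues are clipped at zero against roundoff.  Note that the
  spectrum's rotation invariance only holds when no atom pair sits exactly
  on the cutoff; lattice-regular fixtures can place many pairs there, so
  analyses should avoid cutoffs commensurate with the wall spacing.
* PDB output rounds to 3 decimals (format precision); round-trip tests use
  1e-3 A tolerances accordingly.
* Zero-length paths, empty pathways, unscored individuals and mismatched
  pooling objectives raise immediately rather than propagating NaNs.

## Desk-scale problem sizes

The shipped checks (test suite and `scripts/acceptance.py`) run the tube
searches at population 12 with 40–50 generations against random baselines of
equal evaluation count, 10^4 random walks for the geometry invariants, 10^7
Monte-Carlo samples for the lens-volume oracle, 1000 random populations for
the sorting oracle, and 20 planner seeds on the holed-wall toy.  These sizes
keep a full run in a few minutes on one core while leaving each comparison
statistically unambiguous; production campaigns on real systems use the
Table-style defaults (500–1000 generations, multiple seeded runs pooled by
`pool_pareto`).

## Known limitations

* No force-field minimisation of deformed receptors; rotamer and mode
  combinations can be locally strained.
* Backbone-independent, heavily reduced rotamer table; no loop modelling.
* The Vina-form term is used as a relative profile along a pathway, not as a
  binding free energy.
* Refinement explores rigid poses only; torsional degrees of freedom are
  frozen during bridging.
* Exit-route classification is a generic nearest-direction labeller; any
  system-specific channel nomenclature must be supplied by the user as
  reference vectors.
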