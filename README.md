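# ligpath

Identification of ligand binding and unbinding pathways through proteins by
a multi-objective genetic algorithm, with full-atom ligand and receptor
flexibility.

Protein–ligand docking answers *where* a ligand sits; it says nothing about
*how* it gets there, yet the route — squeezing past a selectivity filter,
opening a side-chain gate — is often what discriminates substrates.
`ligpath` sits between cavity-search tools and long molecular-dynamics
simulations: it evolves explicit, atomistic trajectories of the ligand
through the receptor and scores them with fast structural objectives.  It is
aimed at structural bioinformaticians and molecular modellers who want
channel/egress hypotheses for a prepared receptor–ligand pair in minutes to
hours on one core.

## Method

A candidate solution is a **pathway**: an ordered set of frames, each fixing
the ligand pose and the receptor state.  The genotype bundles

* ligand COM waypoints under two constraints — consecutive step ≤ *max_step*
  (automatic from ligand size, clamped to [0.5, 1] Å) and distance-to-origin
  increment ≥ *min_increment* (default 0.8 Å; lower or negative values admit
  curved routes, at more frames);
* free rigid orientation and free rotation of rotatable dihedrals per frame
  (rotatable = both atoms non-terminal, one typed C3/N3/C2/N2/P, not in a
  ring);
* receptor flexibility at two scales: amplitudes on low-frequency
  anisotropic-network-model (ANM) modes of the Cα trace, and side-chain
  rotamer choices for residues within 5 Å of the ligand at each frame.

Frames are scored by up to three minimised objectives, aggregated over the
pathway by mean or maximum:

| objective | definition | units |
|---|---|---|
| clashes | Σ pairwise vdW sphere-overlap (exact lens volume) in a 5 Å zone around the ligand and mutated rotamers | Å³ |
| vina | AutoDock Vina functional form (gauss1, gauss2, repulsion, hydrophobic, hbond on d = r − R1 − R2, published weights, 8 Å cutoff), intermolecular heavy-atom pairs only | kcal/mol |
| smoothness | max(0, RMSD − cutoff) between consecutive ligand conformations, no superposition | Å |

NSGA-II (population 12; 500/750/1000 generations for 1/2/3 objectives;
crossover 0.2, mutation 0.8) evolves the population and accumulates a Pareto
archive of non-dominated pathways.  An optional RRT-Connect stage bridges
any frame pair whose straight-line interpolation violates a clash threshold,
yielding a continuum-valid trajectory.  See `docs/methods.md` for the full
model, parameter table and limitations.

## Worked example

Search a synthetic constricted channel (a tube of carbon pseudo-atoms with a
1.5 Å bottleneck at mid-height) for the least-clashing crossing of a 1.7 Å
probe atom.  Everything is generated by the package — no downloads:

```bash
ligpath fixtures bottleneck_tube --out channel.pdb
ligpath fixtures single_atom --out probe.mol2
```

`demo.yaml`:

```yaml
receptor: channel.pdb
ligand: probe.mol2
output: demo
seed: 1
genes:
  path: {mode: two_point, origin: [0, 0, -2.0], destination: [0, 0, 32.0],
         min_increment: 0.0, max_step: 1.0}
  torsion: {enabled: false}
objectives:
  - {type: clashes, aggregation: maximum}
ga: {generations: 50}
```

```bash
ligpath run demo.yaml
```

The run directory `demo/seed_1/` contains `pareto.csv`:

```
 solution  n_frames          dir  clashes
        0        46 solution_000 1.010211
```

One archived pathway of 46 frames whose **worst** frame overlaps the wall by
1.01 Å³ — the geometric toll of the bottleneck (a 1.7 Å probe through a
1.5 Å constriction cannot pass overlap-free; a 2.5 Å bottleneck yields
0 Å³).  `solution_000/` holds the multi-model PDB trajectory plus a
per-frame score table (`scores.csv`: frame index, clash Å³, Vina kcal/mol,
smoothness Å, ligand COM).  Re-running with the same seed reproduces the CSV
bit-for-bit.  Typical follow-ups:

```bash
ligpath run demo.yaml --seed 2 --out demo/seed_2   # independent runs...
ligpath pool demo/seed_1 demo/seed_2 --out pooled.csv   # ...pooled Pareto front
ligpath refine demo/seed_1 --solution 0            # continuum refinement
```

For a real system, prepare the inputs as separate receptor and ligand
PDB/mol2 files (single chain, solvent stripped, explicit hydrogens — they
are required for Vina donor/acceptor typing) and enable the receptor genes:

```yaml
genes:
  normalmodes: {enabled: true, n_modes: 5, max_amplitude: 3.0}
  rotamers: {enabled: true, radius: 5.0}
objectives:
  - {type: clashes, aggregation: average}
  - {type: vina, aggregation: average}
```

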