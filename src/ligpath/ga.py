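"""NSGA-II multi-objective evolutionary engine and the pathway genotype.

The engine is generic: any object implementing the small :class:`Problem`
protocol (random genome, mutation, crossover, evaluation to a minimised
objective vector) can be evolved.  :class:`PathwaySearch` is the problem used
in production: its genome bundles the ligand translation path with per-frame
orientation quaternions, torsion angles, normal-mode amplitudes and rotamer
choices; evaluation realizes every frame in Cartesian space and scores it.

Selection follows standard NSGA-II: fast non-dominated sorting into fronts,
crowding distance within fronts, binary tournaments on (rank, crowding) and
elitist environmental selection from parents plus offspring.  Offspring are
made, per individual, by crossover with probability ``p_crossover``, else
mutation with probability ``p_mutation``, else a plain copy.  Rank-1
individuals of every generation feed a cumulative Pareto archive.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Any, Callable, Optional, Protocol, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from . import pathgen
from .chem import Molecule, detect_rotatable_bonds
from .flexibility import (NormalModeBasis, TorsionGene, apply_torsions,
                          compute_normal_modes, load_rotamer_library,
                          vicinity_residues, CHI_ATOMS, assign_rotamers)
from .scoring import Frame, FrameScores, FrameScorer, ObjectiveSpec, aggregate

logger = logging.getLogger("ligpath")

__all__ = [
    "GAConfig",
    "Individual",
    "ParetoArchive",
    "Problem",
    "dominates",
    "non_dominated_sort",
    "crowding_distance",
    "evolve",
    "PathwaySearch",
    "PathGenome",
    "default_generations",
]

_WORST_SCORE = 1e6


def default_generations(n_objectives: int) -> int:
    """500 / 750 / 1000 generations for 1 / 2 / 3 objectives."""
    return {1: 500, 2: 750}.get(n_objectives, 1000)


@dataclass
class GAConfig:
    population_size: int = 12
    generations: Optional[int] = None    # default depends on objective count
    p_crossover: float = 0.2
    p_mutation: float = 0.8
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.p_crossover + self.p_mutation > 1.0 + 1e-12:
            raise ValueError("p_crossover + p_mutation must be <= 1 "
                             "(per-offspring operator choice probabilities)")


@dataclass
class Individual:
    genome: Any
    scores: Optional[np.ndarray] = None
    rank: int = 0          # 1 = non-dominated front
    crowding: float = 0.0
    order: int = 0         # insertion order, deterministic tie-break


class Problem(Protocol):
    n_objectives: int

    def random_individual(self, rng: np.random.Generator) -> Any: ...
    def mutate(self, genome: Any, rng: np.random.Generator) -> Any: ...
    def crossover(self, a: Any, b: Any, rng: np.random.Generator) -> tuple[Any, Any]: ...
    def evaluate(self, genome: Any) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# NSGA-II primitives
# ---------------------------------------------------------------------------

def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """Pareto dominance for minimisation: a <= b everywhere, < somewhere."""
    return bool(np.all(a <= b) and np.any(a < b))


def non_dominated_sort(population: Sequence[Individual]) -> list[list[Individual]]:
    """Fast non-dominated sort; assigns ``rank`` (1-based) on each individual."""
    for ind in population:
        if ind.scores is None:
            raise ValueError("unscored individual in non_dominated_sort")
    n = len(population)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    n_dominating = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(population[i].scores, population[j].scores):
                dominated_by[i].append(j)
                n_dominating[j] += 1
            elif dominates(population[j].scores, population[i].scores):
                dominated_by[j].append(i)
                n_dominating[i] += 1
    fronts: list[list[Individual]] = []
    current = [i for i in range(n) if n_dominating[i] == 0]
    rank = 1
    while current:
        for i in current:
            population[i].rank = rank
        fronts.append([population[i] for i in current])
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                n_dominating[j] -= 1
                if n_dominating[j] == 0:
                    nxt.append(j)
        current = nxt
        rank += 1
    return fronts


def crowding_distance(front: Sequence[Individual]) -> np.ndarray:
    """NSGA-II crowding distance; boundary individuals get +inf.

    An objective with zero range across the front contributes 0 (avoids 0/0).
    Distances are also stored on the individuals.
    """
    n = len(front)
    dist = np.zeros(n)
    if n <= 2:
        dist[:] = np.inf
    else:
        scores = np.array([ind.scores for ind in front])
        for k in range(scores.shape[1]):
            order = np.argsort(scores[:, k], kind="stable")
            lo, hi = scores[order[0], k], scores[order[-1], k]
            dist[order[0]] = dist[order[-1]] = np.inf
            if hi - lo <= 0:
                continue
            gaps = (scores[order[2:], k] - scores[order[:-2], k]) / (hi - lo)
            dist[order[1:-1]] += gaps
    for ind, d in zip(front, dist):
        ind.crowding = float(d)
    return dist


class ParetoArchive:
    """Cumulative pool of mutually non-dominated individuals."""

    def __init__(self) -> None:
        self.members: list[Individual] = []

    def update(self, candidates: Sequence[Individual]) -> None:
        for cand in candidates:
            if cand.scores is None:
                continue
            if any(dominates(m.scores, cand.scores) or
                   np.array_equal(m.scores, cand.scores) for m in self.members):
                continue
            self.members = [m for m in self.members
                            if not dominates(cand.scores, m.scores)]
            self.members.append(copy.deepcopy(cand))

    def best(self, objective: int = 0) -> Individual:
        return min(self.members, key=lambda m: m.scores[objective])

    def scores_array(self) -> np.ndarray:
        return np.array([m.scores for m in self.members])

    def __len__(self) -> int:
        return len(self.members)


def _environmental_selection(combined: list[Individual], k: int) -> list[Individual]:
    fronts = non_dominated_sort(combined)
    selected: list[Individual] = []
    for front in fronts:
        crowding_distance(front)
        if len(selected) + len(front) <= k:
            selected.extend(sorted(front, key=lambda x: -x.order))
        else:
            # ties resolved toward newer individuals: allows neutral drift
            # across score plateaus while staying deterministic
            rest = sorted(front, key=lambda x: (-x.crowding, -x.order))
            selected.extend(rest[: k - len(selected)])
            break
    return selected


def _tournament(pop: list[Individual], rng: np.random.Generator) -> Individual:
    i, j = rng.integers(len(pop)), rng.integers(len(pop))
    a, b = pop[int(i)], pop[int(j)]
    if (a.rank, -a.crowding, a.order) <= (b.rank, -b.crowding, b.order):
        return a
    return b


def _evaluate(problem: Problem, ind: Individual) -> None:
    try:
        ind.scores = np.asarray(problem.evaluate(ind.genome), dtype=float)
    except Exception as exc:
        logger.warning("evaluation failed (%s); assigning worst-case scores", exc)
        ind.scores = np.full(problem.n_objectives, _WORST_SCORE)


def evolve(problem: Problem, config: GAConfig,
           rng: Optional[np.random.Generator] = None,
           callback: Optional[Callable[[int, list[Individual], ParetoArchive], None]] = None,
           ) -> ParetoArchive:
    """Run the NSGA-II loop and return the accumulated Pareto archive.

    Fully reproducible for a fixed seed: every stochastic choice draws from
    the single ``rng`` (built from ``config.seed`` when not supplied).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_gen = config.generations if config.generations is not None \
        else default_generations(problem.n_objectives)

    order = 0
    pop: list[Individual] = []
    for _ in range(config.population_size):
        pop.append(Individual(problem.random_individual(rng), order=order))
        order += 1
    for ind in pop:
        _evaluate(problem, ind)
    for front in non_dominated_sort(pop):
        crowding_distance(front)
    archive = ParetoArchive()
    archive.update([ind for ind in pop if ind.rank == 1])

    for gen in range(n_gen):
        offspring: list[Individual] = []
        for _ in range(config.population_size):
            r = rng.random()
            if r < config.p_crossover:
                p1, p2 = _tournament(pop, rng), _tournament(pop, rng)
                child, _ = problem.crossover(copy.deepcopy(p1.genome),
                                             copy.deepcopy(p2.genome), rng)
            elif r < config.p_crossover + config.p_mutation:
                child = problem.mutate(copy.deepcopy(_tournament(pop, rng).genome), rng)
            else:
                child = copy.deepcopy(_tournament(pop, rng).genome)
            offspring.append(Individual(child, order=order))
            order += 1
        for ind in offspring:
            _evaluate(problem, ind)
        pop = _environmental_selection(pop + offspring, config.population_size)
        archive.update([ind for ind in pop if ind.rank == 1])
        if callback is not None:
            callback(gen, pop, archive)
    return archive


# ---------------------------------------------------------------------------
# the pathway search problem
# ---------------------------------------------------------------------------

@dataclass
class PathGenome:
    """Genotype of one candidate pathway.

    Per-frame lists have length ``len(path.points) + 1``: frame 0 is the
    ligand at the path origin.  ``rotamers`` holds one integer per
    rotamer-capable receptor residue per frame; -1 keeps the native side
    chain.
    """

    path: pathgen.PathPoints
    orientations: list[np.ndarray] = field(default_factory=list)  # quaternions (x,y,z,w)
    torsions: list[np.ndarray] = field(default_factory=list)
    amplitudes: list[np.ndarray] = field(default_factory=list)
    rotamers: list[np.ndarray] = field(default_factory=list)
    # evaluation annotation (not genetic material): per-frame clash of the
    # last scoring pass, used to target local mutations at the worst frames
    frame_clashes: Optional[np.ndarray] = None

    @property
    def n_frames(self) -> int:
        return len(self.path.points) + 1

    def positions(self) -> np.ndarray:
        return np.vstack([self.path.origin[None], self.path.points])


class PathwaySearch:
    """Bridges structures, genes and objectives into a :class:`Problem`.

    Which genes are active is data-driven: torsions need rotatable bonds,
    normal modes need an ANM basis, rotamers need library-capable residues.
    The ligand's internal coordinates are taken relative to its centre of
    mass; a frame pose is torsions, then rigid rotation, then translation of
    the COM onto the waypoint.
    """

    def __init__(self, ligand: Molecule, receptor: Optional[Molecule],
                 objectives: Sequence[ObjectiveSpec],
                 mode: str = "unbinding",
                 origin: Optional[np.ndarray] = None,
                 destination: Optional[np.ndarray] = None,
                 min_increment: float = 0.8,
                 max_step: Optional[float] = None,
                 use_torsions: bool = True,
                 use_normal_modes: bool = False,
                 nma_cutoff: float = 15.0, nma_n_modes: int = 5,
                 nma_max_amplitude: float = 3.0,
                 use_rotamers: bool = False, rotamer_radius: float = 5.0):
        self.ligand = ligand
        self.receptor = receptor
        self.objectives = list(objectives)
        self.n_objectives = len(self.objectives)
        self.mode = mode
        self.min_increment = min_increment
        self.max_step = max_step if max_step is not None else pathgen.auto_max_step(ligand)
        self.origin = np.asarray(origin, dtype=float) if origin is not None \
            else ligand.center_of_mass()
        self.destination = None if destination is None else np.asarray(destination, dtype=float)
        self.stop_predicate = (pathgen.default_stop_predicate(receptor)
                               if mode == "unbinding" and receptor is not None else None)

        self.rot_bonds = detect_rotatable_bonds(ligand) if use_torsions else []
        self.nma_basis: Optional[NormalModeBasis] = None
        self.nma_max_amplitude = nma_max_amplitude
        if use_normal_modes and receptor is not None:
            self.nma_basis = compute_normal_modes(receptor, nma_cutoff, nma_n_modes)
        self.rotamer_radius = rotamer_radius
        self.rotamer_library = load_rotamer_library() if use_rotamers else None
        self.capable_residues: list[tuple[str, str]] = []
        if use_rotamers and receptor is not None:
            seen = []
            for i in range(receptor.n_atoms):
                key = (str(receptor.chains[i]), str(receptor.resids[i]))
                if key not in seen and str(receptor.resnames[i]) in CHI_ATOMS:
                    seen.append(key)
            self.capable_residues = seen

        need_vina = any(o.type == "vina" for o in self.objectives)
        radius = next((o.radius for o in self.objectives if o.type == "clashes"), 5.0)
        self.scorer = FrameScorer(ligand, receptor, eval_radius=radius, need_vina=need_vina)
        self._lig_local = ligand.coords - ligand.center_of_mass()
        self._receptor_static = self.nma_basis is None and not use_rotamers

    # -- genome construction ------------------------------------------------

    def _rand_quat(self, rng: np.random.Generator) -> np.ndarray:
        return Rotation.random(random_state=np.random.RandomState(
            int(rng.integers(2 ** 31)))).as_quat()

    def _rand_frame_genes(self, rng: np.random.Generator) -> dict:
        out = {"orientation": self._rand_quat(rng)}
        if self.rot_bonds:
            out["torsion"] = rng.uniform(-180.0, 180.0, size=len(self.rot_bonds))
        if self.nma_basis is not None:
            out["amplitude"] = rng.normal(0.0, 0.3 * self.nma_max_amplitude,
                                          size=self.nma_basis.n_modes)
        if self.capable_residues:
            out["rotamer"] = np.where(rng.random(len(self.capable_residues)) < 0.2,
                                      rng.integers(0, 3, len(self.capable_residues)), -1)
        return out

    def random_individual(self, rng: np.random.Generator) -> PathGenome:
        path = pathgen.init_path(self.mode, origin=self.origin,
                                 destination=self.destination,
                                 min_increment=self.min_increment,
                                 max_step=self.max_step,
                                 stop_predicate=self.stop_predicate,
                                 rng=rng, receptor=self.receptor)
        g = PathGenome(path)
        self._sync_frame_genes(g, rng)
        return g

    def _sync_frame_genes(self, g: PathGenome, rng: np.random.Generator) -> None:
        """Grow/shrink per-frame gene lists to match the path length."""
        n = g.n_frames
        for _ in range(n - len(g.orientations)):
            fg = self._rand_frame_genes(rng)
            g.orientations.append(fg["orientation"])
            if self.rot_bonds:
                g.torsions.append(fg["torsion"])
            if self.nma_basis is not None:
                g.amplitudes.append(fg["amplitude"])
            if self.capable_residues:
                g.rotamers.append(fg["rotamer"])
        del g.orientations[n:], g.torsions[n:], g.amplitudes[n:], g.rotamers[n:]

    # -- variation ----------------------------------------------------------

    def mutate(self, g: PathGenome, rng: np.random.Generator) -> PathGenome:
        kinds = ["path"]
        if self.ligand.n_atoms > 1:
            kinds.append("orientation")   # a point ligand has no orientation
        if self.rot_bonds:
            kinds.append("torsion")
        if self.nma_basis is not None:
            kinds.append("amplitude")
        if self.capable_residues:
            kinds.append("rotamer")
        kind = kinds[int(rng.integers(len(kinds)))]
        n = g.n_frames
        if kind == "path":
            # mixture of move scales: local jitter polishes single frames,
            # tail resampling reroutes, full resampling reseeds (immigrant)
            r = rng.random()
            if r < 0.6:
                for _ in range(int(rng.integers(1, 4))):
                    idx = self._worst_frame_index(g, rng)
                    g.path = pathgen.perturb_waypoint(g.path, rng, index=idx)
            elif r < 0.9:
                g.path = pathgen.mutate_path(g.path, rng)
            else:
                g.path = pathgen.init_path(
                    self.mode, origin=self.origin, destination=self.destination,
                    min_increment=self.min_increment, max_step=self.max_step,
                    stop_predicate=self.stop_predicate, rng=rng,
                    receptor=self.receptor)
            self._sync_frame_genes(g, rng)
        elif kind == "orientation":
            t = int(rng.integers(n))
            # small random rotation composed onto the current orientation
            delta = Rotation.from_rotvec(rng.normal(0, np.radians(30), 3))
            g.orientations[t] = (delta * Rotation.from_quat(g.orientations[t])).as_quat()
        elif kind == "torsion":
            t = int(rng.integers(n))
            g.torsions[t] = ((g.torsions[t] + rng.normal(0, 30.0, len(self.rot_bonds))
                              + 180.0) % 360.0) - 180.0
        elif kind == "amplitude":
            t = int(rng.integers(n))
            g.amplitudes[t] = np.clip(
                g.amplitudes[t] + rng.normal(0, 0.1 * self.nma_max_amplitude,
                                             self.nma_basis.n_modes),
                -self.nma_max_amplitude, self.nma_max_amplitude)
        elif kind == "rotamer":
            t = int(rng.integers(n))
            r = int(rng.integers(len(self.capable_residues)))
            g.rotamers[t][r] = int(rng.integers(-1, 3))
        return g

    def _worst_frame_index(self, g: PathGenome, rng: np.random.Generator):
        """Waypoint index biased toward the frames with the highest clash of
        the parent's last evaluation; None (uniform) without annotation."""
        fc = g.frame_clashes
        if fc is None or len(fc) != g.n_frames or fc[1:].sum() <= 0:
            return None
        w = fc[1:]  # waypoint t corresponds to frame t+1 (frame 0 = origin)
        if rng.random() < 0.3:
            return None
        return int(rng.choice(len(w), p=w / w.sum()))

    def crossover(self, a: PathGenome, b: PathGenome,
                  rng: np.random.Generator) -> tuple[PathGenome, PathGenome]:
        """Path splice plus per-frame blending of the continuous genes."""
        pa, pb = pathgen.crossover_paths(a.path, b.path, rng)
        a.path, b.path = pa, pb
        n_shared = min(len(a.torsions), len(b.torsions))
        if self.rot_bonds and n_shared:
            w = rng.random()
            for t in range(n_shared):
                ta, tb = a.torsions[t], b.torsions[t]
                a.torsions[t] = w * ta + (1 - w) * tb
                b.torsions[t] = (1 - w) * ta + w * tb
        n_shared = min(len(a.amplitudes), len(b.amplitudes))
        if self.nma_basis is not None and n_shared:
            w = rng.random()
            for t in range(n_shared):
                aa, ab = a.amplitudes[t], b.amplitudes[t]
                a.amplitudes[t] = w * aa + (1 - w) * ab
                b.amplitudes[t] = (1 - w) * aa + w * ab
        if self.capable_residues:
            for t in range(min(len(a.rotamers), len(b.rotamers))):
                swap = rng.random(len(self.capable_residues)) < 0.5
                ra, rb = a.rotamers[t].copy(), b.rotamers[t].copy()
                a.rotamers[t][swap], b.rotamers[t][swap] = rb[swap], ra[swap]
        self._sync_frame_genes(a, rng)
        self._sync_frame_genes(b, rng)
        return a, b

    # -- realization & evaluation -------------------------------------------

    def realize(self, g: PathGenome) -> list[Frame]:
        frames: list[Frame] = []
        positions = g.positions()
        for t in range(g.n_frames):
            if self.rot_bonds and g.torsions:
                lig = apply_torsions(self.ligand,
                                     TorsionGene(self.rot_bonds, g.torsions[t]))
                local = lig.coords - lig.center_of_mass()
            else:
                local = self._lig_local
            rot = Rotation.from_quat(g.orientations[t]) if g.orientations else None
            lig_coords = (rot.apply(local) if rot is not None else local) + positions[t]

            rec_coords = None
            mutated: tuple = ()
            if self.nma_basis is not None:
                from .flexibility import deform
                rec_coords = deform(self.receptor, self.nma_basis, g.amplitudes[t],
                                    self.nma_max_amplitude).coords
            if self.capable_residues and g.rotamers:
                base = self.receptor if rec_coords is None else self.receptor.with_coords(rec_coords)
                vic = vicinity_residues(base, lig_coords, self.rotamer_radius)
                choices = {key: int(g.rotamers[t][r])
                           for r, key in enumerate(self.capable_residues)
                           if key in vic and g.rotamers[t][r] >= 0}
                if choices:
                    rec_coords = assign_rotamers(base, lig_coords, self.rotamer_radius,
                                                 self.rotamer_library, choices).coords
                    mutated = tuple(choices)
                elif rec_coords is None and not self._receptor_static:
                    rec_coords = base.coords
            frames.append(Frame(lig_coords, rec_coords, mutated))
        return frames

    def evaluate(self, g: PathGenome) -> np.ndarray:
        frames = self.realize(g)
        per_frame: list[FrameScores] = []
        smooth_cut = next((o.cutoff for o in self.objectives if o.type == "smoothness"), 1.0)
        want = {o.type for o in self.objectives}
        for t, fr in enumerate(frames):
            fs = FrameScores()
            if "clashes" in want:
                fs.clashes = self.scorer.clash(fr.ligand_coords, fr.receptor_coords,
                                               fr.mutated_residues)
            if "vina" in want:
                fs.vina = self.scorer.vina(fr.ligand_coords, fr.receptor_coords)
            if "smoothness" in want and t > 0:
                fs.smoothness = self.scorer.smoothness(frames[t - 1].ligand_coords,
                                                       fr.ligand_coords, smooth_cut)
            fr.scores = {"clashes": fs.clashes, "vina": fs.vina, "smoothness": fs.smoothness}
            per_frame.append(fs)
        if "clashes" in want:
            g.frame_clashes = np.array([fs.clashes for fs in per_frame])
        return aggregate(per_frame, self.objectives)
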