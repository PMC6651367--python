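"""YAML recipe parsing, run orchestration and cross-run Pareto analysis.

A *recipe* is a plain-text YAML file naming the two structures, the active
genes, the objectives and the GA parameters of one search.  ``run`` executes
it end to end (load, evolve, serialize archive); ``pool_pareto`` merges the
archives of several independent seeded runs into one non-dominated pool,
which is how multi-run campaigns are analysed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import chem, pathgen
from .ga import GAConfig, PathwaySearch, default_generations, dominates, evolve
from .scoring import ObjectiveSpec, Pathway

logger = logging.getLogger("ligpath")

__all__ = [
    "Recipe",
    "RecipeError",
    "parse_recipe",
    "parse_recipe_dict",
    "run",
    "pool_pareto",
    "classify_exit_route",
]


class RecipeError(ValueError):
    """Invalid or inconsistent recipe configuration."""


_TOP_KEYS = {"receptor", "ligand", "output", "seed", "genes", "objectives", "ga", "refine"}
_GENE_KEYS = {"path", "torsion", "normalmodes", "rotamers"}
_PATH_KEYS = {"mode", "origin", "destination", "min_increment", "max_step"}
_NM_KEYS = {"enabled", "cutoff", "n_modes", "max_amplitude"}
_ROT_KEYS = {"enabled", "radius"}
_TOR_KEYS = {"enabled", "atom_types"}
_GA_KEYS = {"population", "generations", "p_crossover", "p_mutation"}
_OBJ_KEYS = {"type", "aggregation", "radius", "cutoff"}
_REFINE_KEYS = {"step_size", "max_iterations", "threshold"}


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise RecipeError(f"unknown key(s) {sorted(unknown)} in {where}")


@dataclass
class Recipe:
    ligand: str
    receptor: Optional[str] = None
    output: str = "runs"
    seed: int = 0
    mode: str = "unbinding"
    origin: Optional[list[float]] = None
    destination: Optional[list[float]] = None
    min_increment: float = 0.8
    max_step: Optional[float] = None          # None = automatic from ligand size
    use_torsions: bool = True
    use_normalmodes: bool = False
    nma_cutoff: float = 15.0
    nma_n_modes: int = 5
    nma_max_amplitude: float = 3.0
    use_rotamers: bool = False
    rotamer_radius: float = 5.0
    objectives: list[ObjectiveSpec] = field(default_factory=list)
    ga: GAConfig = field(default_factory=GAConfig)
    refine_step_size: float = 0.25
    refine_max_iterations: int = 2000
    refine_threshold: float = 50.0

    def to_dict(self) -> dict:
        return {
            "receptor": self.receptor, "ligand": self.ligand,
            "output": self.output, "seed": self.seed,
            "genes": {
                "path": {"mode": self.mode, "origin": self.origin,
                         "destination": self.destination,
                         "min_increment": self.min_increment,
                         "max_step": self.max_step},
                "torsion": {"enabled": self.use_torsions},
                "normalmodes": {"enabled": self.use_normalmodes,
                                "cutoff": self.nma_cutoff,
                                "n_modes": self.nma_n_modes,
                                "max_amplitude": self.nma_max_amplitude},
                "rotamers": {"enabled": self.use_rotamers,
                             "radius": self.rotamer_radius},
            },
            "objectives": [{"type": o.type, "aggregation": o.aggregation,
                            "radius": o.radius, "cutoff": o.cutoff}
                           for o in self.objectives],
            "ga": {"population": self.ga.population_size,
                   "generations": self.ga.generations,
                   "p_crossover": self.ga.p_crossover,
                   "p_mutation": self.ga.p_mutation},
            "refine": {"step_size": self.refine_step_size,
                       "max_iterations": self.refine_max_iterations,
                       "threshold": self.refine_threshold},
        }


def parse_recipe(path: str | Path) -> Recipe:
    """Parse and validate a YAML recipe file, filling the GA defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise RecipeError(f"{path}: recipe must be a YAML mapping")
    return parse_recipe_dict(data)


def parse_recipe_dict(data: dict) -> Recipe:
    _check_keys(data, _TOP_KEYS, "recipe")
    if "ligand" not in data or not data["ligand"]:
        raise RecipeError("recipe must name a ligand structure")

    genes = data.get("genes") or {}
    _check_keys(genes, _GENE_KEYS, "genes")
    path_g = genes.get("path") or {}
    _check_keys(path_g, _PATH_KEYS, "genes.path")
    tor_g = genes.get("torsion") or {}
    _check_keys(tor_g, _TOR_KEYS, "genes.torsion")
    nm_g = genes.get("normalmodes") or {}
    _check_keys(nm_g, _NM_KEYS, "genes.normalmodes")
    rot_g = genes.get("rotamers") or {}
    _check_keys(rot_g, _ROT_KEYS, "genes.rotamers")

    objs_raw = data.get("objectives") or []
    if not objs_raw:
        raise RecipeError("recipe needs at least one objective")
    objectives = []
    for o in objs_raw:
        if isinstance(o, str):
            o = {"type": o}
        _check_keys(o, _OBJ_KEYS, "objectives[]")
        objectives.append(ObjectiveSpec(**o))
    types = [o.type for o in objectives]
    if "vina" in types and "clashes" not in types:
        raise RecipeError(
            "the vina objective only scores intermolecular interactions; "
            "it has to be combined with a clashes evaluation")
    if len(types) != len(set(types)):
        raise RecipeError("duplicate objective types")

    ga_raw = data.get("ga") or {}
    _check_keys(ga_raw, _GA_KEYS, "ga")
    ga = GAConfig(
        population_size=int(ga_raw.get("population", 12)),
        generations=(int(ga_raw["generations"])
                     if ga_raw.get("generations") is not None
                     else default_generations(len(objectives))),
        p_crossover=float(ga_raw.get("p_crossover", 0.2)),
        p_mutation=float(ga_raw.get("p_mutation", 0.8)),
        seed=int(data.get("seed", 0)),
    )

    ref_raw = data.get("refine") or {}
    _check_keys(ref_raw, _REFINE_KEYS, "refine")

    mode = path_g.get("mode", "unbinding")
    if mode not in pathgen.MODES:
        raise RecipeError(f"unknown path mode {mode!r}")

    return Recipe(
        ligand=str(data["ligand"]),
        receptor=data.get("receptor"),
        output=str(data.get("output", "runs")),
        seed=int(data.get("seed", 0)),
        mode=mode,
        origin=path_g.get("origin"),
        destination=path_g.get("destination"),
        min_increment=float(path_g.get("min_increment", 0.8)),
        max_step=(float(path_g["max_step"]) if path_g.get("max_step") is not None else None),
        use_torsions=bool(tor_g.get("enabled", True)),
        use_normalmodes=bool(nm_g.get("enabled", False)),
        nma_cutoff=float(nm_g.get("cutoff", 15.0)),
        nma_n_modes=int(nm_g.get("n_modes", 5)),
        nma_max_amplitude=float(nm_g.get("max_amplitude", 3.0)),
        use_rotamers=bool(rot_g.get("enabled", False)),
        rotamer_radius=float(rot_g.get("radius", 5.0)),
        objectives=objectives,
        ga=ga,
        refine_step_size=float(ref_raw.get("step_size", 0.25)),
        refine_max_iterations=int(ref_raw.get("max_iterations", 2000)),
        refine_threshold=float(ref_raw.get("threshold", 50.0)),
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def build_search(recipe: Recipe, ligand: Optional[chem.Molecule] = None,
                 receptor: Optional[chem.Molecule] = None) -> PathwaySearch:
    """Load structures (unless supplied) and assemble the search problem."""
    if ligand is None:
        ligand = chem.read_structure(recipe.ligand, role="ligand")
    if receptor is None and recipe.receptor:
        receptor = chem.read_structure(recipe.receptor, role="receptor")
    return PathwaySearch(
        ligand, receptor, recipe.objectives,
        mode=recipe.mode,
        origin=None if recipe.origin is None else np.asarray(recipe.origin, float),
        destination=None if recipe.destination is None else np.asarray(recipe.destination, float),
        min_increment=recipe.min_increment,
        max_step=recipe.max_step,
        use_torsions=recipe.use_torsions,
        use_normal_modes=recipe.use_normalmodes,
        nma_cutoff=recipe.nma_cutoff, nma_n_modes=recipe.nma_n_modes,
        nma_max_amplitude=recipe.nma_max_amplitude,
        use_rotamers=recipe.use_rotamers, rotamer_radius=recipe.rotamer_radius,
    )


def run(recipe: Recipe, run_dir: Optional[str | Path] = None,
        ligand: Optional[chem.Molecule] = None,
        receptor: Optional[chem.Molecule] = None) -> Path:
    """Execute one seeded GA run; returns the run directory.

    The directory holds ``recipe.yaml`` (config echo), ``run.log`` (seed and
    one line of per-generation objective minima), ``pareto.csv`` (one row per
    archive member) and one trajectory directory per archive member.
    """
    run_dir = Path(run_dir) if run_dir is not None else Path(recipe.output) / f"seed_{recipe.seed}"
    run_dir.mkdir(parents=True, exist_ok=True)

    search = build_search(recipe, ligand, receptor)
    rng = np.random.default_rng(recipe.seed)

    log_lines = [f"seed: {recipe.seed}",
                 "config: " + json.dumps(recipe.to_dict(), default=str)]

    def on_generation(gen, pop, archive):
        mins = np.min([ind.scores for ind in pop], axis=0)
        stamp = " ".join(f"{o.type}={v:.3f}" for o, v in zip(recipe.objectives, mins))
        log_lines.append(f"gen {gen + 1} {stamp} archive={len(archive)}")

    archive = evolve(search, recipe.ga, rng=rng, callback=on_generation)

    (run_dir / "recipe.yaml").write_text(yaml.safe_dump(recipe.to_dict()))
    (run_dir / "run.log").write_text("\n".join(log_lines) + "\n")

    rows = []
    for k, member in enumerate(archive.members):
        sol_dir = run_dir / f"solution_{k:03d}"
        frames = search.realize(member.genome)
        pw = Pathway(search.ligand, search.receptor, frames, recipe.objectives,
                     member.scores)
        _attach_frame_scores(search, pw)
        chem.write_trajectory(pw, sol_dir)
        row = {"solution": k, "n_frames": len(frames), "dir": sol_dir.name}
        for o, v in zip(recipe.objectives, member.scores):
            row[o.type] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(run_dir / "pareto.csv", index=False)
    return run_dir


def _attach_frame_scores(search: PathwaySearch, pw: Pathway) -> None:
    want = {o.type for o in pw.objectives}
    cut = next((o.cutoff for o in pw.objectives if o.type == "smoothness"), 1.0)
    for t, fr in enumerate(pw.frames):
        fr.scores = {
            "clashes": search.scorer.clash(fr.ligand_coords, fr.receptor_coords,
                                           fr.mutated_residues) if "clashes" in want else None,
            "vina": search.scorer.vina(fr.ligand_coords, fr.receptor_coords)
            if "vina" in want else None,
            "smoothness": search.scorer.smoothness(pw.frames[t - 1].ligand_coords,
                                                   fr.ligand_coords, cut)
            if "smoothness" in want and t > 0 else None,
        }


def pool_pareto(run_dirs: Sequence[str | Path]) -> pd.DataFrame:
    """Non-dominated subset of the union of several runs' archives.

    All runs must have been scored under the same objective definitions.
    """
    tables = []
    obj_cols: Optional[list[str]] = None
    for d in run_dirs:
        df = pd.read_csv(Path(d) / "pareto.csv")
        cols = [c for c in df.columns if c in ("clashes", "vina", "smoothness")]
        if obj_cols is None:
            obj_cols = cols
        elif cols != obj_cols:
            raise RecipeError(f"{d}: objectives {cols} do not match {obj_cols}")
        df = df.assign(run=str(d))
        tables.append(df)
    pooled = pd.concat(tables, ignore_index=True)
    scores = pooled[obj_cols].to_numpy()
    keep = np.ones(len(pooled), dtype=bool)
    for i in range(len(pooled)):
        for j in range(len(pooled)):
            if i != j and keep[i] and dominates(scores[j], scores[i]):
                keep[i] = False
                break
    return pooled[keep].reset_index(drop=True)


def classify_exit_route(final_com: np.ndarray, receptor_com: np.ndarray,
                        reference_vectors: dict[str, np.ndarray]) -> str:
    """Assign a pathway to the nearest labelled exit direction.

    ``reference_vectors`` maps route labels (user-supplied, system-specific
    nomenclature) to direction vectors from the receptor centre; the pathway's
    final-frame COM direction picks the label with the largest cosine
    similarity.
    """
    v = np.asarray(final_com, float) - np.asarray(receptor_com, float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("final frame COM coincides with the receptor centre")
    v = v / n
    best, best_cos = None, -np.inf
    for label, ref in reference_vectors.items():
        ref = np.asarray(ref, float)
        c = float(np.dot(v, ref) / np.linalg.norm(ref))
        if c > best_cos:
            best, best_cos = label, c
    return best
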