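"""Per-frame pathway objectives and their aggregation.

Three minimised objectives judge a frame:

* **clashes** — summed pairwise van-der-Waals sphere intersection volume
  (A^3) inside a 5 A evaluation zone around the reference atoms (the ligand
  atoms plus the beta carbons of mutated rotamer side chains).  Intermolecular
  ligand/receptor overlap, overlap of mutated side chains with their
  surroundings, and intra-ligand overlap of atom pairs three or more bonds
  apart all contribute; 1-2 and 1-3 pairs are excluded and hydrogens are
  ignored.
* **vina** — an intermolecular binding-energy estimate (kcal/mol) using the
  AutoDock Vina functional form (gauss1, gauss2, repulsion, hydrophobic,
  hbond on the surface distance d = r - R1 - R2, published weights, 8 A
  cutoff).  No torsion/rotor penalty: only ligand-receptor heavy-atom pairs
  enter, so it must be paired with the clash objective to remain physical.
* **smoothness** — max(0, RMSD - cutoff) between consecutive ligand
  conformations, computed on raw coordinates without superposition so that
  rigid flips are penalised alongside conformational jumps.

A pathway's score per objective is the average or the maximum over frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .chem import Molecule, StructureError

__all__ = [
    "FrameScores",
    "ObjectiveSpec",
    "Frame",
    "Pathway",
    "sphere_overlap_volume",
    "clash_score",
    "vina_score",
    "smoothness_score",
    "aggregate",
    "FrameScorer",
    "assign_vina_types",
    "VINA_WEIGHTS",
    "VINA_XS_RADII",
]

OBJECTIVE_TYPES = ("clashes", "vina", "smoothness")


@dataclass
class ObjectiveSpec:
    """One active objective: its type, aggregation mode and parameters."""

    type: str
    aggregation: str = "average"
    radius: float = 5.0       # clash evaluation zone
    cutoff: float = 1.0       # smoothness permissiveness (A)

    def __post_init__(self) -> None:
        if self.type not in OBJECTIVE_TYPES:
            raise ValueError(f"unknown objective type {self.type!r}")
        if self.aggregation not in ("average", "maximum"):
            raise ValueError(f"aggregation must be average|maximum, got {self.aggregation!r}")


@dataclass
class FrameScores:
    """Raw per-frame objective values (smoothness is None for frame 0)."""

    clashes: Optional[float] = None
    vina: Optional[float] = None
    smoothness: Optional[float] = None

    def get(self, key: str, default=None):
        return getattr(self, key, default) if getattr(self, key) is not None else default


@dataclass
class Frame:
    """One realized pathway point: ligand pose plus receptor state."""

    ligand_coords: np.ndarray
    receptor_coords: Optional[np.ndarray] = None
    mutated_residues: tuple = ()
    scores: Optional[dict] = None


@dataclass
class Pathway:
    """Ordered frames with per-frame and aggregated objective scores."""

    ligand: Molecule
    receptor: Optional[Molecule]
    frames: list[Frame]
    objectives: list[ObjectiveSpec] = field(default_factory=list)
    objective_values: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# sphere overlap
# ---------------------------------------------------------------------------

def sphere_overlap_volume(r1: float, r2: float, d: float) -> float:
    """Exact intersection volume (A^3) of two spheres at centre distance d.

    The standard two-sphere lens: zero beyond contact, the smaller sphere's
    volume under full containment, and
    ``pi (r1+r2-d)^2 (d^2 + 2d(r1+r2) - 3(r1-r2)^2) / (12 d)`` between.
    """
    return float(_overlap_vec(np.atleast_1d(float(r1)), np.atleast_1d(float(r2)),
                              np.atleast_1d(float(d)))[0])


def _overlap_vec(r1: np.ndarray, r2: np.ndarray, d: np.ndarray) -> np.ndarray:
    r1, r2, d = np.broadcast_arrays(r1, r2, d)
    out = np.zeros_like(d, dtype=float)
    rmin = np.minimum(r1, r2)
    contained = d <= np.abs(r1 - r2)
    out[contained] = 4.0 / 3.0 * np.pi * rmin[contained] ** 3
    lens = (~contained) & (d < r1 + r2)
    if np.any(lens):
        a, b, dd = r1[lens], r2[lens], d[lens]
        out[lens] = (np.pi * (a + b - dd) ** 2 *
                     (dd ** 2 + 2 * dd * (a + b) - 3 * (a - b) ** 2)) / (12 * dd)
    return out


# ---------------------------------------------------------------------------
# Vina functional form
# ---------------------------------------------------------------------------

# published term weights (kcal/mol)
VINA_WEIGHTS = {
    "gauss1": -0.035579,
    "gauss2": -0.005156,
    "repulsion": 0.840245,
    "hydrophobic": -0.035069,
    "hbond": -0.587439,
}

VINA_CUTOFF = 8.0  # A, on the interatomic distance

# Vina's heavy-atom (XS) radii, A
VINA_XS_RADII = {
    "C": 1.9, "N": 1.8, "O": 1.7, "S": 2.0, "P": 2.1,
    "F": 1.5, "Cl": 1.8, "Br": 2.0, "I": 2.2,
}
_DEFAULT_XS_RADIUS = 1.9

_HALOGENS = ("F", "Cl", "Br", "I")


@dataclass
class VinaTypes:
    """Heavy-atom typing for the Vina terms."""

    heavy: np.ndarray        # indices of heavy atoms in the molecule
    radii: np.ndarray        # XS radius per heavy atom
    hydrophobic: np.ndarray  # bool per heavy atom
    donor: np.ndarray        # bool per heavy atom (N/O bearing an H)
    acceptor: np.ndarray     # bool per heavy atom (N or O)


def assign_vina_types(mol: Molecule) -> VinaTypes:
    """Type heavy atoms as hydrophobic / H-bond donor / acceptor.

    Carbon is hydrophobic unless bonded to N or O; halogens are hydrophobic.
    Donors are N/O with at least one bound hydrogen (explicit hydrogens are
    required: a molecule containing N or O but no H at all is rejected);
    acceptors are all N and O.
    """
    has_no = any(e in ("N", "O") for e in mol.elements)
    has_h = any(e == "H" for e in mol.elements)
    if has_no and not has_h:
        raise StructureError(
            "explicit hydrogens are required for Vina donor/acceptor typing "
            "but none are present")
    heavy = np.where(mol.heavy_mask)[0]
    radii = np.array([VINA_XS_RADII.get(mol.elements[i], _DEFAULT_XS_RADIUS) for i in heavy])
    hyd = np.zeros(len(heavy), dtype=bool)
    don = np.zeros(len(heavy), dtype=bool)
    acc = np.zeros(len(heavy), dtype=bool)
    for k, i in enumerate(heavy):
        e = mol.elements[i]
        nbr_elems = [mol.elements[j] for j in mol.adjacency[i]]
        if e == "C":
            hyd[k] = not any(x in ("N", "O") for x in nbr_elems)
        elif e in _HALOGENS:
            hyd[k] = True
        if e in ("N", "O"):
            acc[k] = True
            don[k] = "H" in nbr_elems
    return VinaTypes(heavy, radii, hyd, don, acc)


def _vina_pair_energy(d_surf: np.ndarray, hh: np.ndarray, hb: np.ndarray) -> float:
    """Sum of weighted Vina terms on surface distances d_surf."""
    g1 = np.exp(-((d_surf / 0.5) ** 2))
    g2 = np.exp(-(((d_surf - 3.0) / 2.0) ** 2))
    rep = np.where(d_surf < 0, d_surf ** 2, 0.0)
    phob = np.clip((1.5 - d_surf) / 1.0, 0.0, 1.0) * hh
    hbond = np.clip(-d_surf / 0.7, 0.0, 1.0) * hb
    return float(VINA_WEIGHTS["gauss1"] * g1.sum()
                 + VINA_WEIGHTS["gauss2"] * g2.sum()
                 + VINA_WEIGHTS["repulsion"] * rep.sum()
                 + VINA_WEIGHTS["hydrophobic"] * phob.sum()
                 + VINA_WEIGHTS["hbond"] * hbond.sum())


# ---------------------------------------------------------------------------
# frame scorer
# ---------------------------------------------------------------------------

def _graph_excluded_pairs(mol: Molecule, max_sep: int = 2) -> set[tuple[int, int]]:
    """Atom pairs separated by fewer than ``max_sep + 1`` bonds (1-2 and 1-3)."""
    excl: set[tuple[int, int]] = set()
    for i in range(mol.n_atoms):
        frontier = {i}
        seen = {i}
        for _ in range(max_sep):
            nxt = set()
            for a in frontier:
                for b in mol.adjacency[a]:
                    if b not in seen:
                        nxt.add(b)
                        excl.add((min(i, b), max(i, b)))
            seen |= nxt
            frontier = nxt
    return excl


class FrameScorer:
    """Evaluates clash / vina / smoothness for frames of one ligand-receptor
    system, caching topology-derived quantities and (when the receptor is
    rigid) its spatial index."""

    def __init__(self, ligand: Molecule, receptor: Optional[Molecule] = None,
                 eval_radius: float = 5.0, need_vina: bool = False):
        self.ligand = ligand
        self.receptor = receptor
        self.eval_radius = eval_radius

        self.lig_heavy = np.where(ligand.heavy_mask)[0]
        self.lig_radii = ligand.vdw_radii[self.lig_heavy]
        excl = _graph_excluded_pairs(ligand)
        nh = len(self.lig_heavy)
        pairs = [(a, b) for a in range(nh) for b in range(a + 1, nh)
                 if (min(self.lig_heavy[a], self.lig_heavy[b]),
                     max(self.lig_heavy[a], self.lig_heavy[b])) not in excl]
        self._intra_pairs = np.array(pairs, dtype=int).reshape(-1, 2)

        if receptor is not None:
            self.rec_heavy = np.where(receptor.heavy_mask)[0]
            self.rec_radii = receptor.vdw_radii[self.rec_heavy]
            self._rec_excl = _graph_excluded_pairs(receptor)
            self._static_tree = cKDTree(receptor.coords[self.rec_heavy])
            self._rec_res_keys = [(str(receptor.chains[i]), str(receptor.resids[i]))
                                  for i in self.rec_heavy]
        if need_vina:
            self.lig_vina = assign_vina_types(ligand)
            self.rec_vina = assign_vina_types(receptor) if receptor is not None else None

    # -- clash --------------------------------------------------------------

    def _rec_tree(self, rec_coords: Optional[np.ndarray]):
        if rec_coords is None:
            return self._static_tree, self.receptor.coords[self.rec_heavy]
        xyz = rec_coords[self.rec_heavy]
        return cKDTree(xyz), xyz

    def clash(self, lig_coords: np.ndarray,
              rec_coords: Optional[np.ndarray] = None,
              mutated_residues: Iterable[tuple[str, str]] = ()) -> float:
        """Clash volume (A^3) of one frame; see the module docstring for the
        pair bookkeeping."""
        lig_xyz = lig_coords[self.lig_heavy]
        total = 0.0

        # intra-ligand (1-4 and beyond)
        if len(self._intra_pairs):
            pi, pj = self._intra_pairs[:, 0], self._intra_pairs[:, 1]
            d = np.linalg.norm(lig_xyz[pi] - lig_xyz[pj], axis=1)
            total += _overlap_vec(self.lig_radii[pi], self.lig_radii[pj], d).sum()

        if self.receptor is None:
            return total

        tree, rec_xyz = self._rec_tree(rec_coords)

        # evaluation zone: receptor heavy atoms within eval_radius of a
        # reference atom (ligand atoms + CB of mutated rotamer residues)
        refs = [lig_xyz]
        mutated = set(mutated_residues)
        if mutated:
            cb = [k for k, i in enumerate(self.rec_heavy)
                  if self._rec_res_keys[k] in mutated and self.receptor.names[i] == "CB"]
            if cb:
                refs.append(rec_xyz[cb])
        zone: set[int] = set()
        for ref in refs:
            for lst in tree.query_ball_point(ref, self.eval_radius):
                zone.update(lst)
        if not zone:
            return total
        zone_idx = np.fromiter(zone, dtype=int)

        # ligand <-> zone receptor atoms
        dmat = np.linalg.norm(lig_xyz[:, None, :] - rec_xyz[zone_idx][None, :, :], axis=2)
        total += _overlap_vec(self.lig_radii[:, None], self.rec_radii[zone_idx][None, :], dmat).sum()

        # mutated side chains <-> other zone atoms (intra-receptor)
        if mutated:
            bb = self.receptor.is_backbone
            side = [k for k, i in enumerate(self.rec_heavy)
                    if self._rec_res_keys[k] in mutated and not bb[i]]
            side_set = set(side)
            for k in side:
                for m in zone_idx:
                    m = int(m)
                    if m == k or (m in side_set and m < k):
                        continue  # each mutated-mutated pair once
                    if self._rec_res_keys[m] == self._rec_res_keys[k]:
                        continue  # same residue: internal geometry is library-built
                    gi = int(self.rec_heavy[min(k, m)])
                    gj = int(self.rec_heavy[max(k, m)])
                    if (gi, gj) in self._rec_excl:
                        continue
                    d = float(np.linalg.norm(rec_xyz[k] - rec_xyz[m]))
                    total += sphere_overlap_volume(float(self.rec_radii[k]),
                                                   float(self.rec_radii[m]), d)
        return total

    # -- vina ---------------------------------------------------------------

    def vina(self, lig_coords: np.ndarray,
             rec_coords: Optional[np.ndarray] = None) -> float:
        """Intermolecular Vina score (kcal/mol) of one frame."""
        if self.receptor is None:
            return 0.0
        lt, rt = self.lig_vina, self.rec_vina
        lig_xyz = lig_coords[lt.heavy]
        rec_all = self.receptor.coords if rec_coords is None else rec_coords
        rec_xyz = rec_all[rt.heavy]
        tree = self._static_vina_tree(rec_xyz) if rec_coords is None else cKDTree(rec_xyz)

        li, rj, dist = [], [], []
        for a, lst in enumerate(tree.query_ball_point(lig_xyz, VINA_CUTOFF)):
            for b in lst:
                li.append(a)
                rj.append(b)
        if not li:
            return 0.0
        li = np.array(li)
        rj = np.array(rj)
        r = np.linalg.norm(lig_xyz[li] - rec_xyz[rj], axis=1)
        d_surf = r - lt.radii[li] - rt.radii[rj]
        hh = lt.hydrophobic[li] & rt.hydrophobic[rj]
        hb = (lt.donor[li] & rt.acceptor[rj]) | (lt.acceptor[li] & rt.donor[rj])
        return _vina_pair_energy(d_surf, hh, hb)

    def _static_vina_tree(self, rec_xyz: np.ndarray) -> cKDTree:
        if not hasattr(self, "_vina_tree_cache"):
            self._vina_tree_cache = cKDTree(rec_xyz)
        return self._vina_tree_cache

    # -- smoothness ---------------------------------------------------------

    @staticmethod
    def smoothness(prev_coords: np.ndarray, cur_coords: np.ndarray,
                   cutoff: float = 1.0) -> float:
        return smoothness_score(prev_coords, cur_coords, cutoff)


# ---------------------------------------------------------------------------
# module-level convenience forms
# ---------------------------------------------------------------------------

def clash_score(ligand: Molecule, lig_coords: np.ndarray,
                receptor: Optional[Molecule] = None,
                rec_coords: Optional[np.ndarray] = None,
                mutated_residues: Iterable[tuple[str, str]] = (),
                eval_radius: float = 5.0) -> float:
    """One-shot clash volume; builds a throwaway :class:`FrameScorer`."""
    scorer = FrameScorer(ligand, receptor, eval_radius=eval_radius)
    return scorer.clash(np.asarray(lig_coords), rec_coords, mutated_residues)


def vina_score(ligand: Molecule, lig_coords: np.ndarray, receptor: Molecule,
               rec_coords: Optional[np.ndarray] = None) -> float:
    """One-shot intermolecular Vina score."""
    scorer = FrameScorer(ligand, receptor, need_vina=True)
    return scorer.vina(np.asarray(lig_coords), rec_coords)


def smoothness_score(prev_coords: np.ndarray, cur_coords: np.ndarray,
                     cutoff: float = 1.0) -> float:
    """max(0, RMSD - cutoff) on raw coordinates (no superposition)."""
    prev = np.asarray(prev_coords, dtype=float)
    cur = np.asarray(cur_coords, dtype=float)
    if prev.shape != cur.shape:
        raise ValueError(f"atom count mismatch: {prev.shape} vs {cur.shape}")
    rmsd = float(np.sqrt(np.mean(np.sum((prev - cur) ** 2, axis=1))))
    return max(0.0, rmsd - cutoff)


def aggregate(per_frame: Sequence[FrameScores | dict],
              objectives: Sequence[ObjectiveSpec]) -> np.ndarray:
    """Average or maximum of each objective across frames.

    Smoothness is undefined for frame 0 and is skipped there; an empty
    pathway raises.
    """
    if len(per_frame) == 0:
        raise ValueError("cannot aggregate an empty pathway")
    out = np.empty(len(objectives))
    for k, obj in enumerate(objectives):
        vals = []
        for f_idx, fs in enumerate(per_frame):
            v = fs.get(obj.type) if hasattr(fs, "get") else fs[obj.type]
            if v is None:
                if obj.type == "smoothness" and f_idx == 0:
                    continue
                raise ValueError(f"missing {obj.type} score at frame {f_idx}")
            vals.append(v)
        if not vals:
            vals = [0.0]
        out[k] = np.mean(vals) if obj.aggregation == "average" else np.max(vals)
    return out
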