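"""Ligand and receptor flexibility genes.

Three independent degrees of freedom supplement the ligand translation path:

* **Torsions** — free rotation about the ligand's rotatable dihedral bonds.
* **Normal modes** — global receptor deformations from an elastic-network
  (anisotropic network model) analysis of the C-alpha trace.  Low-frequency
  modes approximate collective motions such as domain breathing; a frame's
  receptor conformation is the reference structure displaced along a small
  set of modes by per-mode amplitudes.
* **Rotamers** — local side-chain resampling, restricted to residues in the
  vicinity of the ligand at each frame, driven by a compact
  backbone-independent chi-angle table packaged with the module.

The all-atom extension of the C-alpha modes is a rigid per-residue
translation; no force-field relaxation is applied afterwards.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .chem import Molecule, StructureError

logger = logging.getLogger("ligpath")

__all__ = [
    "TorsionGene",
    "NormalModeBasis",
    "RotamerAssignment",
    "apply_torsions",
    "compute_normal_modes",
    "deform",
    "assign_rotamers",
    "vicinity_residues",
    "load_rotamer_library",
    "measure_dihedral",
    "CHI_ATOMS",
]


# ---------------------------------------------------------------------------
# torsions
# ---------------------------------------------------------------------------

@dataclass
class TorsionGene:
    """Per-rotatable-bond rotation angles in degrees, in [-180, 180)."""

    bond_ids: list[int]
    angles: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float).reshape(-1)
        if len(self.angles) != len(self.bond_ids):
            raise ValueError("angle list length must equal rotatable bond count")


def measure_dihedral(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Signed dihedral angle i-j-k-l in degrees."""
    b0 = coords[i] - coords[j]
    b1 = coords[k] - coords[j]
    b2 = coords[l] - coords[k]
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def apply_torsions(ligand: Molecule, gene: TorsionGene) -> Molecule:
    """Rotate the smaller side of each rotatable bond by the gene angle.

    Rotations are relative (an all-zero gene is the identity); bond lengths
    and all angles outside the rotated substructure are untouched.
    """
    out = ligand.copy()
    for bond_id, angle in zip(gene.bond_ids, gene.angles):
        i, j = ligand.bonds[bond_id]
        if ligand.bond_in_ring(i, j):
            raise ValueError(f"bond {bond_id} ({i}-{j}) is in a ring; not rotatable")
        side_j = out.bond_side(i, j) - {j}
        side_i = out.bond_side(j, i) - {i}
        moving, pivot, other = (side_j, j, i) if len(side_j) <= len(side_i) else (side_i, i, j)
        if not moving:
            continue
        axis = out.coords[pivot] - out.coords[other]
        axis /= np.linalg.norm(axis)
        rot = Rotation.from_rotvec(np.radians(angle) * axis)
        idx = np.array(sorted(moving))
        out.coords[idx] = rot.apply(out.coords[idx] - out.coords[pivot]) + out.coords[pivot]
    return out


# ---------------------------------------------------------------------------
# elastic-network normal modes
# ---------------------------------------------------------------------------

@dataclass
class NormalModeBasis:
    """Non-rigid low-frequency ANM modes of the C-alpha trace.

    ``modes`` has shape (3M, n_modes) with orthonormal columns; ``eigenvalues``
    holds the full ascending spectrum (the first six are the near-zero
    rigid-body modes), ``mode_eigenvalues`` the n_modes retained ones.
    """

    modes: np.ndarray
    eigenvalues: np.ndarray
    mode_eigenvalues: np.ndarray
    n_modes: int
    cutoff: float
    ca_indices: np.ndarray


def _ca_indices(receptor: Molecule) -> np.ndarray:
    return np.where((receptor.names == "CA") & (receptor.elements != "H"))[0]


def compute_normal_modes(receptor: Molecule, cutoff: float = 15.0,
                         n_modes: int = 5) -> NormalModeBasis:
    """Anisotropic network model on the C-alpha atoms.

    Springs of unit force constant connect every C-alpha pair within
    ``cutoff`` A.  The 3M x 3M Hessian is diagonalised exactly; the six
    smallest eigenvalues are the rigid-body null space and the next
    ``n_modes`` eigenvectors are returned as the deformation basis.
    """
    ca = _ca_indices(receptor)
    if len(ca) < 3:
        raise StructureError("need >= 3 C-alpha atoms for normal-mode analysis")
    xyz = receptor.coords[ca]
    m = len(ca)
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(dist2, np.inf)
    contact = dist2 <= cutoff * cutoff

    # connectivity check: a disconnected spring network has > 6 zero modes
    from scipy.sparse.csgraph import connected_components
    n_comp, _ = connected_components(contact, directed=False)
    if n_comp > 1:
        raise StructureError(
            f"elastic network is disconnected at cutoff {cutoff} A "
            f"({n_comp} components); increase the cutoff")

    hess = np.zeros((3 * m, 3 * m))
    for i in range(m):
        js = np.where(contact[i])[0]
        for j in js:
            d = diff[i, j]
            block = -np.outer(d, d) / dist2[i, j]
            hess[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
            hess[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
    evals, evecs = np.linalg.eigh(hess)
    evals = np.clip(evals, 0.0, None)  # numerical noise below zero
    k = min(n_modes, 3 * m - 6)
    modes = evecs[:, 6:6 + k]
    return NormalModeBasis(modes, evals, evals[6:6 + k], k, cutoff, ca)


def deform(receptor: Molecule, basis: NormalModeBasis, amplitudes: Sequence[float],
           max_amplitude: float = 3.0) -> Molecule:
    """Displace the receptor along the mode basis by per-mode amplitudes (A).

    C-alpha atoms move by ``sum_k a_k * mode_k``; every other atom of a residue
    is rigidly translated with its C-alpha.  Amplitudes beyond
    ``max_amplitude`` are clamped with a warning.
    """
    amps = np.asarray(amplitudes, dtype=float).reshape(-1)
    if len(amps) != basis.n_modes:
        raise ValueError(f"expected {basis.n_modes} amplitudes, got {len(amps)}")
    if np.any(np.abs(amps) > max_amplitude):
        logger.warning("normal-mode amplitude clamped to +/-%.1f A", max_amplitude)
        amps = np.clip(amps, -max_amplitude, max_amplitude)

    disp_ca = (basis.modes @ amps).reshape(-1, 3)
    out = receptor.copy()
    # per-residue rigid translation with the residue's C-alpha
    res_of_ca = {}
    for ca_pos, atom_idx in enumerate(basis.ca_indices):
        key = (receptor.chains[atom_idx], receptor.resids[atom_idx])
        res_of_ca[key] = ca_pos
    for i in range(receptor.n_atoms):
        key = (receptor.chains[i], receptor.resids[i])
        if key in res_of_ca:
            out.coords[i] = out.coords[i] + disp_ca[res_of_ca[key]]
    return out


# ---------------------------------------------------------------------------
# rotamers
# ---------------------------------------------------------------------------

# chi dihedral atom-name quadruples for the rotatable side chains;
# GLY/ALA have no chi and PRO's ring is excluded from resampling
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}


@dataclass
class RotamerAssignment:
    """Chosen rotamer index per vicinity residue for one frame."""

    residue_ids: list[tuple[str, str]]   # (chain, resid)
    choices: list[int]
    vicinity_radius: float = 5.0


def load_rotamer_library(path: Optional[str] = None) -> dict[str, list[dict]]:
    """Load the packaged backbone-independent rotamer table.

    A reduced most-probable table (3 rotamers per residue type) with columns
    resname, rotamer, chi1..chi4 (degrees, blank where absent), probability.
    """
    if path is None:
        src = resources.files("ligpath").joinpath("data/rotamers.csv")
        text = src.read_text()
    else:
        text = open(path).read()
    lib: dict[str, list[dict]] = {}
    for row in csv.DictReader(text.splitlines()):
        chis = [float(row[f"chi{k}"]) for k in range(1, 5) if row[f"chi{k}"].strip()]
        lib.setdefault(row["resname"], []).append(
            {"chis": chis, "probability": float(row["probability"])})
    return lib


def vicinity_residues(receptor: Molecule, ligand_coords: np.ndarray,
                      radius: float = 5.0) -> list[tuple[str, str]]:
    """Residues with >= 1 atom within ``radius`` A of any ligand atom."""
    from scipy.spatial import cKDTree

    tree = cKDTree(np.asarray(ligand_coords).reshape(-1, 3))
    d, _ = tree.query(receptor.coords, k=1)
    near = d <= radius
    seen: list[tuple[str, str]] = []
    for i in np.where(near)[0]:
        key = (str(receptor.chains[i]), str(receptor.resids[i]))
        if key not in seen:
            seen.append(key)
    return seen


def assign_rotamers(receptor: Molecule, ligand_frame: Molecule | np.ndarray,
                    vicinity_radius: float = 5.0,
                    library: Optional[Mapping[str, list[dict]]] = None,
                    choices: Optional[Mapping[tuple[str, str], int]] = None) -> Molecule:
    """Rebuild vicinity side chains at library chi angles.

    ``choices`` maps (chain, resid) to a rotamer index; vicinity residues
    without an entry, and residue types absent from the library (GLY, ALA,
    PRO, non-standard), are left untouched.  Backbone coordinates are
    preserved exactly.
    """
    lig_xyz = ligand_frame.coords if isinstance(ligand_frame, Molecule) else np.asarray(ligand_frame)
    library = load_rotamer_library() if library is None else library
    choices = choices or {}
    out = receptor.copy()
    res_index = receptor.residue_index()
    for key in vicinity_residues(receptor, lig_xyz, vicinity_radius):
        if key not in choices:
            continue
        atoms = res_index.get(f"{key[0]}:{key[1]}")
        if atoms is None:
            continue
        resname = str(receptor.resnames[atoms[0]])
        if resname not in library or resname not in CHI_ATOMS:
            continue
        rot = library[resname][choices[key] % len(library[resname])]
        _set_side_chain(out, atoms, resname, rot["chis"])
    return out


def _set_side_chain(mol: Molecule, res_atoms: np.ndarray, resname: str,
                    chis: Sequence[float]) -> None:
    """Rotate side-chain atoms of one residue to the target chi angles."""
    name_to_idx = {str(mol.names[i]): int(i) for i in res_atoms}
    res_set = set(int(i) for i in res_atoms)
    for chi_target, quad in zip(chis, CHI_ATOMS[resname]):
        try:
            a, b, c, d = (name_to_idx[n] for n in quad)
        except KeyError:
            return  # incomplete side chain
        current = measure_dihedral(mol.coords, a, b, c, d)
        delta = chi_target - current
        moving = (mol.bond_side(b, c) - {c}) & res_set
        if not moving:
            continue
        axis = mol.coords[c] - mol.coords[b]
        axis /= np.linalg.norm(axis)
        rot = Rotation.from_rotvec(np.radians(delta) * axis)
        idx = np.array(sorted(moving))
        mol.coords[idx] = rot.apply(mol.coords[idx] - mol.coords[c]) + mol.coords[c]
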