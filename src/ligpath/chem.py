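"""Molecular structure I/O, radii/typing assignment and rotatable-bond perception.

Structures are read from PDB or mol2 files into a lightweight :class:`Molecule`
container (numpy coordinate block plus per-atom annotation arrays).  Simplified
connectivity-based atom types in the style of Chimera's IDATM scheme (``C3`` =
sp3 carbon, ``N2`` = sp2 nitrogen, ...) drive rotatable-bond detection: a bond
is rotatable when both endpoints are non-terminal heavy atoms, at least one
endpoint is typed C3/N3/C2/N2/P, and the bond is not part of a ring.

Coordinates are in Angstrom throughout.  Atom indices are 0-based internally
and 1-based in emitted PDB serials.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

logger = logging.getLogger("ligpath")

__all__ = [
    "Atom",
    "Molecule",
    "StructureError",
    "read_structure",
    "assign_radii_and_types",
    "detect_rotatable_bonds",
    "write_trajectory",
    "VDW_RADII",
    "DEFAULT_VDW_RADIUS",
]


class StructureError(ValueError):
    """Unparseable, empty or otherwise invalid molecular structure."""


# van der Waals radii (A), Bondi's compilation; used for clash volumes.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
    "B": 1.92, "Si": 2.10, "Se": 1.90,
}
DEFAULT_VDW_RADIUS = 1.70

# Covalent radii (A) for distance-based bond perception on PDB files
# that carry no CONECT records.
_COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
    "B": 0.84, "Si": 1.11, "Se": 1.20,
}
_DEFAULT_COVALENT_RADIUS = 0.77

_ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904, "I": 126.904,
    "B": 10.81, "Si": 28.085, "Se": 78.971,
}

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA"})


@dataclass
class Atom:
    """One atom of a :class:`Molecule` (a convenience view, not the storage)."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    vdw_radius: float
    atom_type: str
    residue_id: str
    residue_name: str
    chain_id: str
    is_backbone: bool


@dataclass
class Molecule:
    """Receptor or ligand: coordinates plus per-atom annotations and bonds.

    ``bonds`` holds 0-based index pairs with ``i < j``.  Annotation arrays all
    have length ``n_atoms``.
    """

    names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    bonds: list[tuple[int, int]]
    role: str = "ligand"
    vdw_radii: Optional[np.ndarray] = None
    atom_types: Optional[np.ndarray] = None
    _adjacency: Optional[list[list[int]]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.n_atoms == 0:
            raise StructureError("molecule has zero atoms")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        for i, j in self.bonds:
            if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise StructureError(f"bond ({i}, {j}) references missing atom")

    # -- basic geometry -----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def masses(self) -> np.ndarray:
        return np.array([_ATOMIC_MASSES.get(e, 12.0) for e in self.elements])

    def center_of_mass(self) -> np.ndarray:
        m = self.masses
        return (self.coords * m[:, None]).sum(axis=0) / m.sum()

    def bounding_radius(self, center: Optional[np.ndarray] = None) -> float:
        """Radius of the bounding sphere about ``center`` (default: COM)."""
        c = self.center_of_mass() if center is None else np.asarray(center)
        return float(np.linalg.norm(self.coords - c, axis=1).max())

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    @property
    def is_backbone(self) -> np.ndarray:
        bb = np.array([n in _BACKBONE_NAMES for n in self.names])
        return bb & (self.resnames != "LIG")

    # -- connectivity -------------------------------------------------------

    @property
    def adjacency(self) -> list[list[int]]:
        if self._adjacency is None:
            adj: list[list[int]] = [[] for _ in range(self.n_atoms)]
            for i, j in self.bonds:
                adj[i].append(j)
                adj[j].append(i)
            self._adjacency = adj
        return self._adjacency

    def heavy_degree(self, i: int) -> int:
        return sum(1 for j in self.adjacency[i] if self.elements[j] != "H")

    def bond_in_ring(self, i: int, j: int) -> bool:
        """True if atoms i-j remain connected after removing the bond."""
        seen = {i}
        stack = [i]
        while stack:
            a = stack.pop()
            for b in self.adjacency[a]:
                if a == i and b == j:
                    continue
                if b == j:
                    return True
                if b not in seen:
                    seen.add(b)
                    stack.append(b)
        return False

    def bond_side(self, i: int, j: int) -> set[int]:
        """Atoms on the j-side of acyclic bond i-j (including j)."""
        seen = {i, j}
        stack = [j]
        side = {j}
        while stack:
            a = stack.pop()
            for b in self.adjacency[a]:
                if b not in seen:
                    seen.add(b)
                    side.add(b)
                    stack.append(b)
        return side

    # -- views & copies -----------------------------------------------------

    def atoms(self) -> Iterable[Atom]:
        radii = self.vdw_radii if self.vdw_radii is not None else np.full(self.n_atoms, np.nan)
        types = self.atom_types if self.atom_types is not None else np.full(self.n_atoms, "", dtype=object)
        bb = self.is_backbone
        for i in range(self.n_atoms):
            yield Atom(i, str(self.names[i]), str(self.elements[i]), self.coords[i],
                       float(radii[i]), str(types[i]), str(self.resids[i]),
                       str(self.resnames[i]), str(self.chains[i]), bool(bb[i]))

    def copy(self) -> "Molecule":
        return Molecule(self.names, self.elements, self.coords.copy(),
                        self.resids, self.resnames, self.chains,
                        list(self.bonds), self.role, self.vdw_radii,
                        self.atom_types, self._adjacency)

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        out = self.copy()
        out.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        return out

    def residue_index(self) -> dict[str, np.ndarray]:
        """Map 'chain:resid' -> atom indices, in file order."""
        keys = [f"{c}:{r}" for c, r in zip(self.chains, self.resids)]
        out: dict[str, list[int]] = {}
        for i, k in enumerate(keys):
            out.setdefault(k, []).append(i)
        return {k: np.array(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL", "H2O"})


def _element_from(name: str, sybyl: str) -> str:
    if sybyl and sybyl != "?":
        el = sybyl.split(".")[0]
        if el.capitalize() in VDW_RADII or len(el) <= 2:
            return el.capitalize()
    # PDB name fallback: strip digits, handle 2-letter halogens
    stripped = "".join(c for c in name if c.isalpha())
    if stripped[:2].capitalize() in ("Cl", "Br"):
        return stripped[:2].capitalize()
    return stripped[:1].upper() if stripped else "C"


def read_structure(path: str | Path, format: Optional[str] = None,
                   role: str = "ligand", strip_solvent: bool = True) -> Molecule:
    """Read a PDB or mol2 file into a :class:`Molecule`.

    Only the first MODEL of a multi-model PDB is used (a warning is logged).
    Alternate locations other than blank/'A' are dropped.  Bonds come from the
    mol2 bond block or PDB CONECT records; PDB files without CONECT fall back
    to covalent-radius distance perception (sum of covalent radii x 1.2).
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("pdb", "mol2"):
        raise StructureError(f"unsupported format: {fmt!r}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format=fmt, topology_format=fmt)
        except Exception as exc:  # unparseable under the named standard
            raise StructureError(f"cannot parse {path} as {fmt}: {exc}") from exc

        if hasattr(u.trajectory, "n_frames") and u.trajectory.n_frames > 1:
            logger.warning("%s has %d models; using the first", path, u.trajectory.n_frames)
        u.trajectory[0]

        atoms = u.atoms
        if hasattr(atoms, "altLocs"):
            keep = np.isin(atoms.altLocs, ("", " ", "A"))
            atoms = atoms[keep]
        if strip_solvent and hasattr(atoms, "resnames"):
            atoms = atoms[~np.isin(atoms.resnames, list(_WATER_RESNAMES))]
        if len(atoms) == 0:
            raise StructureError(f"{path}: no atoms left after filtering")

        names = atoms.names.astype(object)
        sybyl = atoms.types.astype(object) if fmt == "mol2" else np.full(len(atoms), "", dtype=object)
        try:
            elements = atoms.elements.astype(object)
            elements = np.array([e.capitalize() if e else _element_from(n, t)
                                 for e, n, t in zip(elements, names, sybyl)], dtype=object)
        except Exception:
            elements = np.array([_element_from(n, t) for n, t in zip(names, sybyl)], dtype=object)

        coords = atoms.positions.astype(float)
        resids = atoms.resids.astype(str).astype(object)
        resnames = atoms.resnames.astype(object) if hasattr(atoms, "resnames") else np.full(len(atoms), "LIG", dtype=object)
        try:
            chains = atoms.chainIDs.astype(object)
        except Exception:
            chains = np.full(len(atoms), "A", dtype=object)

        index_of = {a.ix: i for i, a in enumerate(atoms)}
        bonds: list[tuple[int, int]] = []
        if hasattr(u, "bonds") and len(u.bonds):
            for bi, bj in u.bonds.to_indices():
                if bi in index_of and bj in index_of:
                    i, j = index_of[bi], index_of[bj]
                    bonds.append((min(i, j), max(i, j)))

    if not bonds and len(coords) > 1:
        bonds = _perceive_bonds(coords, elements)

    mol = Molecule(names, elements, coords, resids, resnames, chains,
                   sorted(set(bonds)), role=role)
    return assign_radii_and_types(mol)


def _perceive_bonds(coords: np.ndarray, elements: np.ndarray) -> list[tuple[int, int]]:
    """Covalent-radius criterion: bonded if d <= 1.2 * (r_cov_i + r_cov_j)."""
    from scipy.spatial import cKDTree

    rcov = np.array([_COVALENT_RADII.get(e, _DEFAULT_COVALENT_RADIUS) for e in elements])
    tree = cKDTree(coords)
    maxd = 1.2 * 2 * rcov.max()
    bonds = []
    for i, j in tree.query_pairs(maxd):
        d = np.linalg.norm(coords[i] - coords[j])
        if 0.4 < d <= 1.2 * (rcov[i] + rcov[j]):
            bonds.append((min(i, j), max(i, j)))
    return bonds


# ---------------------------------------------------------------------------
# radii and simplified atom typing
# ---------------------------------------------------------------------------

def assign_radii_and_types(mol: Molecule) -> Molecule:
    """Assign vdW radii and simplified connectivity-based atom types in place.

    Types follow the IDATM-style convention restricted to what rotatable-bond
    perception needs: ``C3``/``C2``/``C1`` by coordination of carbon, ``N3``/
    ``N2``/``N1`` for nitrogen, ``O3``/``O1``, ``S3``/``S1``, ``P``; other
    elements keep their element symbol.  Unknown elements get the fallback
    radius with a warning.
    """
    radii = np.empty(mol.n_atoms)
    for i, e in enumerate(mol.elements):
        if e in VDW_RADII:
            radii[i] = VDW_RADII[e]
        else:
            logger.warning("unknown element %r: fallback vdW radius %.2f A", e, DEFAULT_VDW_RADIUS)
            radii[i] = DEFAULT_VDW_RADIUS

    types = np.empty(mol.n_atoms, dtype=object)
    for i, e in enumerate(mol.elements):
        deg = len(mol.adjacency[i])
        if e == "C":
            types[i] = "C3" if deg >= 4 or deg == 0 else ("C2" if deg == 3 else "C1")
        elif e == "N":
            types[i] = "N3" if deg >= 3 else ("N2" if deg == 2 else "N1")
        elif e == "O":
            types[i] = "O3" if deg >= 2 else "O1"
        elif e == "S":
            types[i] = "S3" if deg >= 2 else "S1"
        elif e == "P":
            types[i] = "P"
        else:
            types[i] = e
    mol.vdw_radii = radii
    mol.atom_types = types
    return mol


_ROTATABLE_TYPES = frozenset({"C3", "N3", "C2", "N2", "P"})


def detect_rotatable_bonds(mol: Molecule) -> list[int]:
    """Indices into ``mol.bonds`` of the rotatable bonds.

    A bond rotates when both endpoints are non-terminal heavy atoms (>= 2 heavy
    neighbours each), at least one endpoint is typed C3, N3, C2, N2 or P, and
    the bond is not in a ring.
    """
    if mol.atom_types is None:
        raise StructureError("atom types not assigned; call assign_radii_and_types first")
    out = []
    for b, (i, j) in enumerate(mol.bonds):
        if mol.elements[i] == "H" or mol.elements[j] == "H":
            continue
        if mol.heavy_degree(i) < 2 or mol.heavy_degree(j) < 2:
            continue
        if mol.atom_types[i] not in _ROTATABLE_TYPES and mol.atom_types[j] not in _ROTATABLE_TYPES:
            continue
        if mol.bond_in_ring(i, j):
            continue
        out.append(b)
    return out


# ---------------------------------------------------------------------------
# trajectory output
# ---------------------------------------------------------------------------

def _pdb_atom_line(serial: int, name: str, resname: str, chain: str, resid: str,
                   xyz: np.ndarray, element: str, het: bool) -> str:
    record = "HETATM" if het else "ATOM  "
    name_f = f" {name:<3s}" if len(name) < 4 else name[:4]
    try:
        resid_i = int(resid)
    except ValueError:
        resid_i = 1
    return (f"{record}{serial % 100000:5d} {name_f} {resname[:3]:>3s} {chain[:1] or 'A'}"
            f"{resid_i % 10000:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {element[:2]:>2s}")


def write_trajectory(pathway, out_dir: str | Path) -> dict[str, Path]:
    """Write a pathway as a multi-model PDB plus a per-frame score CSV.

    One MODEL per frame holds the receptor followed by the ligand (HETATM).
    ``scores.csv`` has one row per frame: index, clash (A^3), vina (kcal/mol),
    smoothness (A) and the ligand centre of mass.
    """
    import pandas as pd

    if not pathway.frames:
        raise ValueError("empty pathway")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create {out_dir}: {exc}") from exc

    receptor = pathway.receptor
    ligand = pathway.ligand
    pdb_path = out_dir / "pathway.pdb"
    lines: list[str] = []
    for f_idx, frame in enumerate(pathway.frames):
        lines.append(f"MODEL     {f_idx + 1:4d}")
        serial = 1
        if receptor is not None:
            rc = frame.receptor_coords if frame.receptor_coords is not None else receptor.coords
            for i in range(receptor.n_atoms):
                lines.append(_pdb_atom_line(serial, str(receptor.names[i]), str(receptor.resnames[i]),
                                            str(receptor.chains[i]), str(receptor.resids[i]),
                                            rc[i], str(receptor.elements[i]), het=False))
                serial += 1
        for i in range(ligand.n_atoms):
            lines.append(_pdb_atom_line(serial, str(ligand.names[i]), "LIG", "L", "1",
                                        frame.ligand_coords[i], str(ligand.elements[i]), het=True))
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    pdb_path.write_text("\n".join(lines) + "\n")

    rows = []
    m = ligand.masses
    for f_idx, frame in enumerate(pathway.frames):
        com = (frame.ligand_coords * m[:, None]).sum(axis=0) / m.sum()
        s = frame.scores or {}
        rows.append({"frame": f_idx,
                     "clash_A3": s.get("clashes", np.nan),
                     "vina_kcal_mol": s.get("vina", np.nan),
                     "smoothness_A": s.get("smoothness", np.nan),
                     "com_x": com[0], "com_y": com[1], "com_z": com[2]})
    csv_path = out_dir / "scores.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return {"pdb": pdb_path, "csv": csv_path}
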