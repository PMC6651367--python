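"""Deterministic synthetic systems with known channels.

Real channel proteins need downloads and hours of search; these generators
build pseudo-receptors and toy ligands with analytically known geometry so
every pipeline stage is testable offline:

* a hollow cylindrical "tube" of pseudo-atoms along z, optionally constricted
  by a bottleneck ring, standing in for a transmembrane channel;
* rigid and torsionally flexible toy ligands (single atom, alkane-like linear
  chain, glycerol-like branched triol);
* an idealized ALA-VAL-ALA tripeptide (synthetic coordinates built from
  standard internal coordinates) for rotamer-gene tests.

All outputs are pure functions of their specs, so snapshots are stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .chem import Molecule, assign_radii_and_types

__all__ = [
    "TubeSpec",
    "make_tube_receptor",
    "make_toy_ligand",
    "make_tripeptide",
    "write_mol2",
    "write_pdb",
]


@dataclass
class TubeSpec:
    """Hollow cylinder along z.  ``inner_radius`` is the free lumen radius:
    wall atom centres sit at inner_radius + atom vdW radius."""

    length: float = 30.0
    inner_radius: float = 4.0
    wall_spacing: float = 2.0
    bottleneck_position: Optional[float] = None   # z of the constriction
    bottleneck_radius: Optional[float] = None     # constricted lumen radius
    atom_radius: float = 1.7                      # carbon vdW

    def __post_init__(self) -> None:
        if self.inner_radius <= 0:
            raise ValueError("inner radius must be positive")
        if self.bottleneck_radius is not None and \
                self.bottleneck_radius >= self.inner_radius:
            raise ValueError("bottleneck radius must be below the inner radius")


def make_tube_receptor(spec: TubeSpec) -> Molecule:
    """Rings of pseudo-atoms forming the tube; every atom is named CA (and so
    belongs to the elastic network) and owns its own residue."""
    coords = []
    z = 0.0
    while z <= spec.length + 1e-9:
        lumen = spec.inner_radius
        if spec.bottleneck_position is not None and \
                abs(z - spec.bottleneck_position) <= spec.wall_spacing:
            lumen = spec.bottleneck_radius
        ring_r = lumen + spec.atom_radius
        n_ring = max(6, int(np.ceil(2 * np.pi * ring_r / spec.wall_spacing)))
        for k in range(n_ring):
            phi = 2 * np.pi * k / n_ring
            coords.append([ring_r * np.cos(phi), ring_r * np.sin(phi), z])
        z += spec.wall_spacing
    coords = np.array(coords)
    n = len(coords)
    mol = Molecule(
        names=np.full(n, "CA", dtype=object),
        elements=np.full(n, "C", dtype=object),
        coords=coords,
        resids=np.array([str(i + 1) for i in range(n)], dtype=object),
        resnames=np.full(n, "TUB", dtype=object),
        chains=np.full(n, "A", dtype=object),
        bonds=[],
        role="receptor",
    )
    return assign_radii_and_types(mol)


# ---------------------------------------------------------------------------
# toy ligands
# ---------------------------------------------------------------------------

_CC = 1.54
_CO = 1.43
_CH = 1.09
_OH = 0.96
_TET = np.radians(109.47)


def _chain_positions(n: int, bond: float = _CC) -> np.ndarray:
    """Planar all-trans zigzag with tetrahedral angles."""
    dx = bond * np.sin(_TET / 2)
    dy = bond * np.cos(_TET / 2)
    return np.array([[i * dx, dy * (i % 2), 0.0] for i in range(n)])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _tetra_completions(center: np.ndarray, nbrs: list[np.ndarray], n_new: int,
                       bond: float) -> list[np.ndarray]:
    """Positions completing an approximately tetrahedral centre."""
    us = [_unit(p - center) for p in nbrs]
    if len(us) == 1:
        u = us[0]
        p1 = _unit(np.cross(u, [0.0, 0.0, 1.0]))
        if np.linalg.norm(np.cross(u, [0.0, 0.0, 1.0])) < 1e-6:
            p1 = _unit(np.cross(u, [0.0, 1.0, 0.0]))
        p2 = np.cross(u, p1)
        out = []
        for k in range(n_new):
            ang = 2 * np.pi * k / 3
            d = _unit(-u / 3 + np.sqrt(8) / 3 * (np.cos(ang) * p1 + np.sin(ang) * p2))
            out.append(center + bond * d)
        return out
    if len(us) == 2:
        b = -_unit(us[0] + us[1])
        p = _unit(np.cross(us[0], us[1]))
        half = np.radians(54.74)
        cands = [center + bond * _unit(b * np.cos(half) + p * np.sin(half)),
                 center + bond * _unit(b * np.cos(half) - p * np.sin(half))]
        return cands[:n_new]
    b = -_unit(sum(us))
    return [center + bond * b][:n_new]


def make_toy_ligand(kind: str = "linear_chain", n_heavy: int = 4) -> Molecule:
    """Build a toy ligand: ``single_atom``, ``linear_chain`` or ``branched``.

    The linear chain of n heavy atoms has n-3 rotatable bonds under the
    terminal/typing rule; the branched variant is a glycerol-like triol.
    """
    if n_heavy < 1:
        raise ValueError("n_heavy must be >= 1")
    names: list[str] = []
    elements: list[str] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []

    def add(name: str, element: str, xyz) -> int:
        names.append(name)
        elements.append(element)
        coords.append(np.asarray(xyz, dtype=float))
        return len(names) - 1

    if kind == "single_atom":
        add("C1", "C", [0.0, 0.0, 0.0])
    elif kind == "linear_chain":
        heavy_pos = _chain_positions(n_heavy)
        heavy_idx = [add(f"C{i+1}", "C", heavy_pos[i]) for i in range(n_heavy)]
        for i in range(n_heavy - 1):
            bonds.append((heavy_idx[i], heavy_idx[i + 1]))
        h_count = 0
        for i in range(n_heavy):
            nbrs = [heavy_pos[j] for j in (i - 1, i + 1) if 0 <= j < n_heavy]
            n_h = 4 - len(nbrs)
            for p in _tetra_completions(heavy_pos[i], nbrs, n_h, _CH):
                h_count += 1
                h = add(f"H{h_count}", "H", p)
                bonds.append((heavy_idx[i], h))
    elif kind == "branched":
        # glycerol-like: C1-C2-C3 backbone, one hydroxyl per carbon
        cpos = _chain_positions(3)
        c_idx = [add(f"C{i+1}", "C", cpos[i]) for i in range(3)]
        bonds.extend([(c_idx[0], c_idx[1]), (c_idx[1], c_idx[2])])
        o_idx = []
        o_pos = []
        for i in range(3):
            nbrs = [cpos[j] for j in (i - 1, i + 1) if 0 <= j < 3]
            spots = _tetra_completions(cpos[i], nbrs, 4 - len(nbrs), _CO)
            o_pos.append(spots[0])
            o = add(f"O{i+1}", "O", spots[0])
            o_idx.append(o)
            bonds.append((c_idx[i], o))
        h_count = 0
        for i in range(3):
            nbrs = [cpos[j] for j in (i - 1, i + 1) if 0 <= j < 3] + [o_pos[i]]
            for p in _tetra_completions(cpos[i], nbrs, 4 - len(nbrs), _CH):
                h_count += 1
                h = add(f"H{h_count}", "H", p)
                bonds.append((c_idx[i], h))
        for i in range(3):
            h_count += 1
            h = add(f"H{h_count}", "H",
                    o_pos[i] + _OH * _unit(o_pos[i] - cpos[i]))
            bonds.append((o_idx[i], h))
    else:
        raise ValueError(f"unknown ligand kind {kind!r}")

    n = len(names)
    mol = Molecule(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        coords=np.array(coords),
        resids=np.full(n, "1", dtype=object),
        resnames=np.full(n, "LIG", dtype=object),
        chains=np.full(n, "L", dtype=object),
        bonds=bonds,
        role="ligand",
    )
    return assign_radii_and_types(mol)


# ---------------------------------------------------------------------------
# tripeptide (synthetic): ALA-VAL-ALA for rotamer tests
# ---------------------------------------------------------------------------

def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D with |CD|=bond, angle(BCD)=angle, dihedral(ABCD)=dihedral."""
    theta = np.radians(angle_deg)
    phi = np.radians(dihedral_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(theta),
                               np.sin(theta) * np.cos(phi),
                               np.sin(theta) * np.sin(phi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_tripeptide(chi1: float = -60.0) -> Molecule:
    """Idealized ALA-VAL-ALA built from standard internal coordinates.

    Synthetic stand-in for a crystallographic fragment: backbone in a
    helix-like (phi, psi) and the VAL side chain at ``chi1`` degrees.  No
    hydrogens (rotamer rebuilding is a heavy-atom operation here).
    """
    pos: dict[str, np.ndarray] = {}
    pos["N1"] = np.array([0.0, 0.0, 0.0])
    pos["CA1"] = np.array([1.458, 0.0, 0.0])
    pos["C1"] = pos["CA1"] + 1.525 * np.array([np.cos(np.radians(69)),
                                               np.sin(np.radians(69)), 0.0])
    pos["O1"] = _nerf(pos["N1"], pos["CA1"], pos["C1"], 1.231, 120.5, 135.0)
    pos["CB1"] = _nerf(pos["C1"], pos["N1"], pos["CA1"], 1.53, 110.5, -122.0)
    pos["N2"] = _nerf(pos["N1"], pos["CA1"], pos["C1"], 1.329, 116.2, -45.0)
    pos["CA2"] = _nerf(pos["CA1"], pos["C1"], pos["N2"], 1.458, 121.7, 180.0)
    pos["C2"] = _nerf(pos["C1"], pos["N2"], pos["CA2"], 1.525, 111.0, -60.0)
    pos["O2"] = _nerf(pos["N2"], pos["CA2"], pos["C2"], 1.231, 120.5, 135.0)
    pos["CB2"] = _nerf(pos["C2"], pos["N2"], pos["CA2"], 1.53, 110.5, -122.0)
    pos["CG1"] = _nerf(pos["N2"], pos["CA2"], pos["CB2"], 1.53, 110.5, chi1)
    pos["CG2"] = _nerf(pos["N2"], pos["CA2"], pos["CB2"], 1.53, 110.5, chi1 + 120.0)
    pos["N3"] = _nerf(pos["N2"], pos["CA2"], pos["C2"], 1.329, 116.2, -45.0)
    pos["CA3"] = _nerf(pos["CA2"], pos["C2"], pos["N3"], 1.458, 121.7, 180.0)
    pos["C3"] = _nerf(pos["C2"], pos["N3"], pos["CA3"], 1.525, 111.0, -60.0)
    pos["O3"] = _nerf(pos["N3"], pos["CA3"], pos["C3"], 1.231, 120.5, 135.0)
    pos["CB3"] = _nerf(pos["C3"], pos["N3"], pos["CA3"], 1.53, 110.5, -122.0)

    order = [("N1", "N", "1", "ALA"), ("CA1", "CA", "1", "ALA"), ("C1", "C", "1", "ALA"),
             ("O1", "O", "1", "ALA"), ("CB1", "CB", "1", "ALA"),
             ("N2", "N", "2", "VAL"), ("CA2", "CA", "2", "VAL"), ("C2", "C", "2", "VAL"),
             ("O2", "O", "2", "VAL"), ("CB2", "CB", "2", "VAL"),
             ("CG1", "CG1", "2", "VAL"), ("CG2", "CG2", "2", "VAL"),
             ("N3", "N", "3", "ALA"), ("CA3", "CA", "3", "ALA"), ("C3", "C", "3", "ALA"),
             ("O3", "O", "3", "ALA"), ("CB3", "CB", "3", "ALA")]
    idx = {key: i for i, (key, *_rest) in enumerate(order)}
    bond_keys = [("N1", "CA1"), ("CA1", "C1"), ("C1", "O1"), ("CA1", "CB1"),
                 ("C1", "N2"), ("N2", "CA2"), ("CA2", "C2"), ("C2", "O2"),
                 ("CA2", "CB2"), ("CB2", "CG1"), ("CB2", "CG2"),
                 ("C2", "N3"), ("N3", "CA3"), ("CA3", "C3"), ("C3", "O3"),
                 ("CA3", "CB3")]
    mol = Molecule(
        names=np.array([name for _, name, _, _ in order], dtype=object),
        elements=np.array([name[0] for _, name, _, _ in order], dtype=object),
        coords=np.array([pos[key] for key, *_ in order]),
        resids=np.array([rid for *_, rid, _ in order], dtype=object),
        resnames=np.array([rn for *_, rn in order], dtype=object),
        chains=np.full(len(order), "A", dtype=object),
        bonds=sorted((min(idx[a], idx[b]), max(idx[a], idx[b])) for a, b in bond_keys),
        role="receptor",
    )
    return assign_radii_and_types(mol)


# ---------------------------------------------------------------------------
# writers for fixture export
# ---------------------------------------------------------------------------

def write_pdb(mol: Molecule, path: str | Path) -> Path:
    """Emit a single-model PDB (valid for re-reading through chem I/O)."""
    from .chem import _pdb_atom_line

    path = Path(path)
    lines = []
    for i in range(mol.n_atoms):
        lines.append(_pdb_atom_line(i + 1, str(mol.names[i]), str(mol.resnames[i]),
                                    str(mol.chains[i]), str(mol.resids[i]),
                                    mol.coords[i], str(mol.elements[i]),
                                    het=mol.role == "ligand"))
    for i, j in mol.bonds:
        lines.append(f"CONECT{i + 1:5d}{j + 1:5d}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


_SYBYL = {"C": "C.3", "N": "N.3", "O": "O.3", "S": "S.3", "P": "P.3", "H": "H"}


def write_mol2(mol: Molecule, path: str | Path) -> Path:
    """Emit a minimal TRIPOS mol2 with the bond block."""
    path = Path(path)
    lines = ["@<TRIPOS>MOLECULE", "LIG",
             f"{mol.n_atoms} {len(mol.bonds)} 1", "SMALL", "USER_CHARGES",
             "@<TRIPOS>ATOM"]
    for i in range(mol.n_atoms):
        x, y, z = mol.coords[i]
        lines.append(f"{i + 1:>4d} {mol.names[i]:<4s} {x:>9.4f} {y:>9.4f} {z:>9.4f} "
                     f"{_SYBYL.get(str(mol.elements[i]), str(mol.elements[i])):<5s} "
                     f"1 LIG 0.0000")
    lines.append("@<TRIPOS>BOND")
    for k, (i, j) in enumerate(mol.bonds):
        lines.append(f"{k + 1:>4d} {i + 1:>4d} {j + 1:>4d} 1")
    path.write_text("\n".join(lines) + "\n")
    return path
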