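import numpy as np
import pytest

from ligpath import fixtures as fx
from ligpath.chem import Molecule, assign_radii_and_types


@pytest.fixture(scope="session")
def tube():
    return fx.make_tube_receptor(fx.TubeSpec())


@pytest.fixture(scope="session")
def narrow_tube():
    return fx.make_tube_receptor(fx.TubeSpec(bottleneck_position=15.0,
                                             bottleneck_radius=1.5))


@pytest.fixture(scope="session")
def wide_tube():
    return fx.make_tube_receptor(fx.TubeSpec(bottleneck_position=15.0,
                                             bottleneck_radius=2.5))


@pytest.fixture(scope="session")
def atom_ligand():
    return fx.make_toy_ligand("single_atom")


@pytest.fixture(scope="session")
def butane():
    return fx.make_toy_ligand("linear_chain", 4)


def pseudo_receptor(coords: np.ndarray, resname: str = "PSD") -> Molecule:
    """Bare pseudo-atom receptor from raw coordinates (one residue per atom)."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    mol = Molecule(
        names=np.full(n, "CA", dtype=object),
        elements=np.full(n, "C", dtype=object),
        coords=coords,
        resids=np.array([str(i + 1) for i in range(n)], dtype=object),
        resnames=np.full(n, resname, dtype=object),
        chains=np.full(n, "A", dtype=object),
        bonds=[],
        role="receptor",
    )
    return assign_radii_and_types(mol)


@pytest.fixture(scope="session")
def holed_wall():
    """Plane of atoms at z=0 with a circular hole of radius 3 A at the origin."""
    pts = [[x, y, 0.0]
           for x in np.arange(-8, 8.1, 1.2)
           for y in np.arange(-8, 8.1, 1.2)
           if np.hypot(x, y) > 3.0]
    return pseudo_receptor(np.array(pts), "WAL")
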