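"""Torsion, elastic-network and rotamer genes."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ligpath import fixtures as fx
from ligpath.chem import StructureError, detect_rotatable_bonds
from ligpath.flexibility import (TorsionGene, apply_torsions, assign_rotamers,
                                 compute_normal_modes, deform, measure_dihedral,
                                 load_rotamer_library, vicinity_residues)


class TestTorsions:
    def test_zero_angles_identity(self, butane):
        rb = detect_rotatable_bonds(butane)
        out = apply_torsions(butane, TorsionGene(rb, np.zeros(len(rb))))
        assert np.allclose(out.coords, butane.coords)

    def test_full_turn_identity(self, butane):
        rb = detect_rotatable_bonds(butane)
        out = apply_torsions(butane, TorsionGene(rb, np.full(len(rb), 360.0)))
        assert np.allclose(out.coords, butane.coords, atol=1e-9)

    def test_butane_dihedral_rotates_by_gene_angle(self, butane):
        rb = detect_rotatable_bonds(butane)
        before = measure_dihedral(butane.coords, 0, 1, 2, 3)
        out = apply_torsions(butane, TorsionGene(rb, [60.0]))
        after = measure_dihedral(out.coords, 0, 1, 2, 3)
        delta = (after - before + 180.0) % 360.0 - 180.0
        assert abs(abs(delta) - 60.0) < 1e-6

    def test_bond_lengths_preserved(self, butane):
        rb = detect_rotatable_bonds(butane)
        out = apply_torsions(butane, TorsionGene(rb, [77.0]))
        for i, j in butane.bonds:
            before = np.linalg.norm(butane.coords[i] - butane.coords[j])
            after = np.linalg.norm(out.coords[i] - out.coords[j])
            assert abs(before - after) < 1e-9

    def test_ring_bond_rejected(self):
        from tests.test_chem import _benzene

        mol = _benzene()
        with pytest.raises(ValueError, match="ring"):
            apply_torsions(mol, TorsionGene([0], [30.0]))


class TestNormalModes:
    def test_six_rigid_body_modes(self, tube):
        basis = compute_normal_modes(tube, cutoff=6.0, n_modes=3)
        ev = basis.eigenvalues
        assert np.all(ev[:6] < 1e-8 * ev[-1])
        assert ev[6] > 1e-6

    def test_modes_orthonormal(self, tube):
        basis = compute_normal_modes(tube, cutoff=6.0, n_modes=4)
        gram = basis.modes.T @ basis.modes
        assert np.allclose(gram, np.eye(4), atol=1e-8)

    def test_spectrum_rotation_invariant(self, tube):
        rot = Rotation.from_euler("xyz", [20, -35, 70], degrees=True)
        moved = tube.with_coords(rot.apply(tube.coords) + [3.0, -1.0, 2.0])
        a = compute_normal_modes(tube, cutoff=6.1, n_modes=3).eigenvalues
        b = compute_normal_modes(moved, cutoff=6.1, n_modes=3).eigenvalues
        assert np.allclose(a, b, atol=1e-8 * max(a.max(), 1.0))

    def test_collinear_triatomic_closed_form(self):
        """A 3-bead chain with unit springs between neighbours has axial
        stiffness eigenvalues {1, 3} (eigenvalues of the 1D path Laplacian)."""
        from tests.conftest import pseudo_receptor

        mol = pseudo_receptor(np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]))
        basis = compute_normal_modes(mol, cutoff=1.5, n_modes=1)
        nonzero = np.sort(basis.eigenvalues[basis.eigenvalues > 1e-10])
        assert np.allclose(nonzero, [1.0, 3.0], atol=1e-9)

    def test_disconnected_network_rejected(self):
        from tests.conftest import pseudo_receptor

        far = pseudo_receptor(np.array([[0, 0, 0], [1.0, 0, 0], [2.0, 0, 0],
                                        [50.0, 0, 0], [51.0, 0, 0], [52.0, 0, 0]]))
        with pytest.raises(StructureError, match="cutoff"):
            compute_normal_modes(far, cutoff=5.0, n_modes=2)

    def test_too_few_calpha_rejected(self, atom_ligand):
        with pytest.raises(StructureError):
            compute_normal_modes(atom_ligand)


class TestDeform:
    def test_zero_amplitudes_identity(self, tube):
        basis = compute_normal_modes(tube, cutoff=6.0, n_modes=3)
        out = deform(tube, basis, [0.0, 0.0, 0.0])
        assert np.allclose(out.coords, tube.coords)

    def test_deformation_is_linear(self, tube):
        basis = compute_normal_modes(tube, cutoff=6.0, n_modes=3)
        plus = deform(tube, basis, [1.0, -0.5, 0.3])
        # applying the negated amplitudes to the reference mirrors the move
        minus = deform(tube, basis, [-1.0, 0.5, -0.3])
        assert np.allclose(plus.coords + minus.coords, 2 * tube.coords, atol=1e-9)

    def test_single_mode_rmsd(self, tube):
        basis = compute_normal_modes(tube, cutoff=6.0, n_modes=1)
        a = 2.0
        out = deform(tube, basis, [a])
        ca = basis.ca_indices
        rmsd = np.sqrt(np.mean(np.sum((out.coords[ca] - tube.coords[ca]) ** 2, axis=1)))
        assert abs(rmsd - a / np.sqrt(len(ca))) < 1e-9

    def test_amplitude_clamped(self, tube):
        basis = compute_normal_modes(tube, cutoff=6.0, n_modes=1)
        big = deform(tube, basis, [99.0], max_amplitude=3.0)
        capped = deform(tube, basis, [3.0], max_amplitude=3.0)
        assert np.allclose(big.coords, capped.coords)

    def test_preserves_atom_count(self, tube):
        basis = compute_normal_modes(tube, cutoff=6.0, n_modes=2)
        assert deform(tube, basis, [1.0, 1.0]).n_atoms == tube.n_atoms


class TestRotamers:
    def test_no_vicinity_no_change(self):
        tri = fx.make_tripeptide()
        far = np.array([[100.0, 100.0, 100.0]])
        out = assign_rotamers(tri, far, 5.0, choices={("A", "2"): 0})
        assert np.allclose(out.coords, tri.coords)

    def test_val_choice_sets_library_chi1(self):
        tri = fx.make_tripeptide(chi1=-60.0)
        lib = load_rotamer_library()
        lig = tri.coords[[10]] + 1.0  # near CG1 of VAL
        out = assign_rotamers(tri, lig, 6.0, choices={("A", "2"): 0})
        chi1 = measure_dihedral(out.coords, 5, 6, 9, 10)  # N-CA-CB-CG1 of VAL
        assert abs(chi1 - lib["VAL"][0]["chis"][0]) < 1e-3

    def test_backbone_untouched(self):
        tri = fx.make_tripeptide(chi1=-60.0)
        lig = tri.coords[[10]] + 1.0
        out = assign_rotamers(tri, lig, 6.0, choices={("A", "2"): 1})
        bb = tri.is_backbone
        assert np.array_equal(out.coords[bb], tri.coords[bb])

    def test_residues_without_library_entry_skipped(self):
        tri = fx.make_tripeptide()
        lig = tri.coords[[1]]  # near ALA 1
        out = assign_rotamers(tri, lig, 6.0, choices={("A", "1"): 0})
        assert np.allclose(out.coords, tri.coords)

    def test_vicinity_recomputed_per_position(self):
        tri = fx.make_tripeptide()
        near = vicinity_residues(tri, tri.coords[[10]], 5.0)
        far = vicinity_residues(tri, tri.coords[[10]] + 50.0, 5.0)
        assert ("A", "2") in near and far == []

    def test_library_complete(self):
        lib = load_rotamer_library()
        assert set(lib) >= {"VAL", "LEU", "ARG", "SER", "PHE"}
        for entries in lib.values():
            assert all(e["probability"] > 0 for e in entries)
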