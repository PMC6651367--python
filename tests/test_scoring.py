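"""Clash volumes, Vina functional form, smoothness and aggregation."""

import numpy as np
import pytest

from ligpath import fixtures as fx
from ligpath.chem import StructureError, assign_radii_and_types
from ligpath.scoring import (FrameScores, FrameScorer, ObjectiveSpec, VINA_WEIGHTS,
                             aggregate, assign_vina_types, clash_score,
                             smoothness_score, sphere_overlap_volume, vina_score)
from tests.conftest import pseudo_receptor


def mc_overlap_volume(r1, r2, d, n_samples, rng):
    """Monte-Carlo oracle: sample the bounding box of sphere 1, count points
    inside both spheres."""
    lo = -r1
    pts = rng.uniform(-r1, r1, size=(n_samples, 3))
    in1 = np.einsum("ij,ij->i", pts, pts) <= r1 * r1
    c2 = np.array([d, 0.0, 0.0])
    q = pts - c2
    in2 = np.einsum("ij,ij->i", q, q) <= r2 * r2
    box = (2 * r1) ** 3
    return box * np.count_nonzero(in1 & in2) / n_samples


class TestSphereOverlap:
    def test_full_containment(self):
        assert sphere_overlap_volume(1.7, 1.7, 0.0) == pytest.approx(
            4 / 3 * np.pi * 1.7 ** 3)
        # smaller sphere inside a bigger one
        assert sphere_overlap_volume(3.0, 1.0, 0.5) == pytest.approx(
            4 / 3 * np.pi * 1.0 ** 3)

    def test_tangent_and_beyond(self):
        assert sphere_overlap_volume(1.7, 1.7, 3.4) == 0.0
        assert sphere_overlap_volume(1.7, 1.7, 10.0) == 0.0

    def test_half_overlap_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        exact = sphere_overlap_volume(1.7, 1.7, 1.7)
        mc = mc_overlap_volume(1.7, 1.7, 1.7, 2_000_000, rng)
        assert abs(mc - exact) / exact < 0.005

    def test_asymmetric_matches_monte_carlo(self):
        rng = np.random.default_rng(1)
        exact = sphere_overlap_volume(1.9, 1.2, 2.0)
        mc = mc_overlap_volume(1.9, 1.2, 2.0, 2_000_000, rng)
        assert abs(mc - exact) / exact < 0.01


def brute_force_clash(ligand, lig_coords, receptor, rec_coords):
    """All-pairs oracle (no zone filter): heavy ligand-receptor pairs plus
    intra-ligand pairs three or more bonds apart."""
    from ligpath.scoring import _graph_excluded_pairs

    lh = np.where(ligand.heavy_mask)[0]
    total = 0.0
    if receptor is not None:
        rh = np.where(receptor.heavy_mask)[0]
        for i in lh:
            for j in rh:
                d = float(np.linalg.norm(lig_coords[i] - rec_coords[j]))
                total += sphere_overlap_volume(float(ligand.vdw_radii[i]),
                                               float(receptor.vdw_radii[j]), d)
    excl = _graph_excluded_pairs(ligand)
    for a in range(len(lh)):
        for b in range(a + 1, len(lh)):
            i, j = int(lh[a]), int(lh[b])
            if (min(i, j), max(i, j)) in excl:
                continue
            d = float(np.linalg.norm(lig_coords[i] - lig_coords[j]))
            total += sphere_overlap_volume(float(ligand.vdw_radii[i]),
                                           float(ligand.vdw_radii[j]), d)
    return total


class TestClash:
    def test_extended_ligand_in_vacuum_is_zero(self):
        lig = fx.make_toy_ligand("linear_chain", 6)
        assert clash_score(lig, lig.coords) == 0.0

    def test_single_pair_reduction(self, atom_ligand):
        rec = pseudo_receptor(np.array([[0.0, 0.0, 0.0]]))
        v = clash_score(atom_ligand, np.array([[0.0, 0.0, 0.0]]), rec)
        assert v == pytest.approx(4 / 3 * np.pi * 1.7 ** 3, abs=1e-9)

    def test_zone_filter_matches_bruteforce_when_all_inside(self):
        """With every receptor atom within the 5 A zone the filtered score
        equals the unfiltered all-pairs oracle."""
        rng = np.random.default_rng(2)
        lig = fx.make_toy_ligand("linear_chain", 4)
        scorer = FrameScorer(lig, None)
        for _ in range(25):
            lig_coords = lig.coords + rng.normal(0, 0.1, lig.coords.shape)
            rec_xyz = lig.center_of_mass() + rng.uniform(-3, 3, size=(12, 3))
            rec = pseudo_receptor(rec_xyz)
            got = clash_score(lig, lig_coords, rec)
            want = brute_force_clash(lig, lig_coords, rec, rec.coords)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    def test_monotone_under_approach(self, atom_ligand):
        prev = -1.0
        for d in np.linspace(4.0, 0.0, 30):
            rec = pseudo_receptor(np.array([[d, 0.0, 0.0]]))
            v = clash_score(atom_ligand, np.array([[0.0, 0.0, 0.0]]), rec)
            assert v >= prev - 1e-12
            prev = v

    def test_bonded_pairs_excluded(self):
        lig = fx.make_toy_ligand("linear_chain", 3)  # 1-2 and 1-3 only
        assert clash_score(lig, lig.coords) == 0.0


class TestVina:
    def _pair_system(self, d_surf):
        """One ligand C vs one receptor C at chosen surface distance."""
        lig = fx.make_toy_ligand("single_atom")
        rec = pseudo_receptor(np.array([[1.9 + 1.9 + d_surf, 0.0, 0.0]]))
        return lig, rec

    def test_gauss1_at_zero_surface_distance(self):
        lig, rec = self._pair_system(0.0)
        v = vina_score(lig, lig.coords, rec)
        # both atoms are hydrophobic carbons: gauss1 + gauss2 + hydrophobic
        expected = (VINA_WEIGHTS["gauss1"] * 1.0
                    + VINA_WEIGHTS["gauss2"] * np.exp(-((0 - 3) / 2) ** 2)
                    + VINA_WEIGHTS["hydrophobic"] * 1.0)
        assert v == pytest.approx(expected, abs=1e-12)

    def test_zero_beyond_cutoff(self):
        lig = fx.make_toy_ligand("single_atom")
        rec = pseudo_receptor(np.array([[8.5, 0.0, 0.0]]))
        assert vina_score(lig, lig.coords, rec) == 0.0

    def test_repulsion_zero_for_positive_surface_distance(self):
        for d_surf in (0.0, 0.5, 2.0):
            lig, rec = self._pair_system(d_surf)
            v = vina_score(lig, lig.coords, rec)
            no_rep = (VINA_WEIGHTS["gauss1"] * np.exp(-(d_surf / 0.5) ** 2)
                      + VINA_WEIGHTS["gauss2"] * np.exp(-((d_surf - 3) / 2) ** 2)
                      + VINA_WEIGHTS["hydrophobic"] * np.clip(1.5 - d_surf, 0, 1))
            assert v == pytest.approx(no_rep, abs=1e-12)

    def test_repulsion_grows_quadratically_on_overlap(self):
        lig, rec = self._pair_system(-0.5)
        lig2, rec2 = self._pair_system(-1.0)
        v1 = vina_score(lig, lig.coords, rec)
        v2 = vina_score(lig2, lig2.coords, rec2)
        rep1 = VINA_WEIGHTS["repulsion"] * 0.25
        rep2 = VINA_WEIGHTS["repulsion"] * 1.0
        assert v2 - rep2 < v1  # dominated by repulsion
        assert v2 > v1

    def test_continuity_at_cutoff(self):
        lig = fx.make_toy_ligand("single_atom")
        just_in = pseudo_receptor(np.array([[7.999, 0.0, 0.0]]))
        just_out = pseudo_receptor(np.array([[8.001, 0.0, 0.0]]))
        vi = vina_score(lig, lig.coords, just_in)
        vo = vina_score(lig, lig.coords, just_out)
        assert vo == 0.0
        assert abs(vi - vo) < 5e-3

    def test_hbond_requires_donor_acceptor(self):
        glc = fx.make_toy_ligand("branched")   # has O-H donors
        t = assign_vina_types(glc)
        assert t.donor.any() and t.acceptor.any()
        # carbons bonded to O are not hydrophobic
        c_near_o = [k for k, i in enumerate(t.heavy) if glc.elements[i] == "C"]
        assert not t.hydrophobic[c_near_o].any()

    def test_missing_hydrogens_rejected(self):
        tri = fx.make_tripeptide()  # N/O present, no hydrogens
        with pytest.raises(StructureError, match="hydrogen"):
            assign_vina_types(tri)


class TestSmoothness:
    def test_identical_frames_zero(self, butane):
        assert smoothness_score(butane.coords, butane.coords, 0.0) == 0.0

    def test_rigid_translation(self, butane):
        moved = butane.coords + [1.0, 0.0, 0.0]
        assert smoothness_score(butane.coords, moved, 0.0) == pytest.approx(1.0)
        assert smoothness_score(butane.coords, moved, 1.0) == 0.0

    def test_flip_scores_worse_than_advance(self):
        """A flipped linear ligand moves its atoms much farther than a smooth
        advance of the same COM displacement."""
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [3.0, 0, 0], [4.5, 0, 0]])
        advanced = coords + [0.0, 0.0, 1.0]
        com = coords.mean(axis=0)
        flipped = (2 * com - coords) + [0.0, 0.0, 1.0]  # end-over-end flip
        s_adv = smoothness_score(coords, advanced, 0.0)
        s_flip = smoothness_score(coords, flipped, 0.0)
        assert s_flip > s_adv

    def test_atom_count_mismatch(self):
        with pytest.raises(ValueError):
            smoothness_score(np.zeros((3, 3)), np.zeros((4, 3)))


class TestAggregate:
    def _frames(self, clashes):
        return [FrameScores(clashes=c) for c in clashes]

    def test_average_and_maximum(self):
        objs_avg = [ObjectiveSpec("clashes", "average")]
        objs_max = [ObjectiveSpec("clashes", "maximum")]
        fs = self._frames([10.0, 20.0, 30.0])
        assert aggregate(fs, objs_avg)[0] == pytest.approx(20.0)
        assert aggregate(fs, objs_max)[0] == pytest.approx(30.0)

    def test_maximum_dominates_average(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            fs = self._frames(rng.uniform(0, 100, size=8).tolist())
            avg = aggregate(fs, [ObjectiveSpec("clashes", "average")])[0]
            mx = aggregate(fs, [ObjectiveSpec("clashes", "maximum")])[0]
            assert mx >= avg

    def test_average_permutation_invariant(self):
        fs = self._frames([5.0, 1.0, 9.0, 2.0])
        objs = [ObjectiveSpec("clashes", "average")]
        assert aggregate(fs, objs)[0] == aggregate(fs[::-1], objs)[0]

    def test_smoothness_skips_first_frame(self):
        fs = [FrameScores(smoothness=None), FrameScores(smoothness=2.0),
              FrameScores(smoothness=4.0)]
        v = aggregate(fs, [ObjectiveSpec("smoothness", "average")])
        assert v[0] == pytest.approx(3.0)

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValueError):
            aggregate([], [ObjectiveSpec("clashes")])
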