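"""Pocket selection spheres, grouped descriptors, volume, pose invariance."""

from __future__ import annotations

import math
import warnings

import numpy as np
import pytest

from raspdplus.pocket_features import (
    ACCEPTOR_GROUP_MAP,
    AROMATIC_RESIDUES,
    DONOR_GROUP_MAP,
    POCKET_FEATURE_NAMES,
    PocketSelection,
    cofactor_in_pocket,
    pocket_descriptors,
    pocket_volume,
    residue_group_descriptors,
    select_pocket,
)
from raspdplus.structio import MolecularGraph, ProteinStructure, Residue
from raspdplus.synthdata import oracle_sphere_volume

CENTER = np.zeros(3)
MAXD = 4.0


def _point_residue(name, atom, element, distance, resnum=1, direction=(1, 0, 0)):
    pos = np.asarray(direction, dtype=float)
    pos = pos / np.linalg.norm(pos) * distance
    return Residue(name, "A", resnum, [(atom, element, pos)])


class TestSelection:
    def test_residue_com_inside_extended_sphere_included(self):
        prot = ProteinStructure([_point_residue("GLY", "N", "N", MAXD + 0.5)])
        sel = select_pocket(prot, CENTER, MAXD)
        assert len(sel.residues_com) == 1

    def test_residue_com_outside_com_sphere_but_atoms_counted(self):
        prot = ProteinStructure([_point_residue("GLY", "N", "N", MAXD + 1.0)])
        sel = select_pocket(prot, CENTER, MAXD)
        assert sel.residues_com == []
        assert len(sel.atoms_hb) == 1  # still within maxD + 3.0

    def test_atom_beyond_hb_sphere_excluded(self):
        prot = ProteinStructure([_point_residue("GLY", "N", "N", MAXD + 3.1)])
        with pytest.warns(UserWarning, match="empty pocket"):
            sel = select_pocket(prot, CENTER, MAXD)
        assert sel.atoms_hb == []

    def test_boundaries_inclusive(self):
        # hb sphere boundary is exactly representable: maxD 4.0 + 3.0 = 7.0
        prot = ProteinStructure([_point_residue("GLY", "N", "N", 7.0)])
        sel = select_pocket(prot, CENTER, MAXD)
        assert len(sel.atoms_hb) == 1

    def test_enlarging_maxd_never_removes_selections(self):
        rng = np.random.default_rng(0)
        residues = [
            _point_residue("GLY", "N", "N", float(d), resnum=i + 1,
                           direction=rng.normal(size=3))
            for i, d in enumerate(rng.uniform(1, 12, size=20))
        ]
        prot = ProteinStructure(residues)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            small = select_pocket(prot, CENTER, 3.0)
            large = select_pocket(prot, CENTER, 6.0)
        ids_small = {(r.chain, r.number) for r in small.residues_com}
        ids_large = {(r.chain, r.number) for r in large.residues_com}
        assert ids_small <= ids_large
        assert len(small.atoms_hb) <= len(large.atoms_hb)

    def test_nonpositive_maxd_rejected(self):
        prot = ProteinStructure([_point_residue("GLY", "N", "N", 3.0)])
        with pytest.raises(ValueError):
            select_pocket(prot, CENTER, 0.0)


class TestGroupDescriptors:
    def test_single_glycine_backbone_only(self, glycine_complex):
        protein, _lig, exp = glycine_complex
        sel = select_pocket(protein, np.asarray(exp["center"]), exp["maxD"])
        raw = residue_group_descriptors(sel)
        assert raw["PD(Amide-NH)"] == 1
        assert raw["PA(Amide-O)"] == 1
        for name, value in raw.items():
            if name.startswith(("PD(", "PA(")) and "Amide" not in name:
                assert value == 0

    def test_single_aspartate_carboxylate_acceptors(self, aspartate_complex):
        protein, _lig, exp = aspartate_complex
        sel = select_pocket(protein, np.asarray(exp["center"]), exp["maxD"])
        raw = residue_group_descriptors(sel)
        assert raw["PA(D+E)"] == 2  # both carboxylate oxygens
        assert raw["PA(Amide-O)"] == 1
        assert raw["PD(Amide-NH)"] == 1
        assert raw["PD(T+S+Y+D+E)"] == 0  # unprotonated Asp does not donate

    def test_mixed_pocket_matches_hand_tabulated_oracle(self, mixed_pocket_complex):
        protein, _lig, exp = mixed_pocket_complex
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_pocket(protein, np.asarray(exp["center"]), exp["maxD"])
            raw = residue_group_descriptors(sel)
        for group, count in exp["pocket_counts_raw"].items():
            assert raw[group] == count, group

    def test_empty_selection_gives_all_zero(self):
        sel = PocketSelection(CENTER, MAXD, [], [])
        raw = residue_group_descriptors(sel)
        assert all(v == 0 for v in raw.values())
        assert len(raw) == 13

    def test_unknown_residue_counted_backbone_only_with_warning(self):
        res = Residue("XYZ", "A", 1, [
            ("N", "N", np.array([1.0, 0, 0])),
            ("O", "O", np.array([0, 1.0, 0])),
            ("QQ1", "O", np.array([0, 0, 1.0])),
        ])
        sel = select_pocket(ProteinStructure([res]), CENTER, MAXD)
        with pytest.warns(UserWarning, match="unknown residue"):
            raw = residue_group_descriptors(sel)
        assert raw["PD(Amide-NH)"] == 1
        assert raw["PA(Amide-O)"] == 1
        assert sum(v for k, v in raw.items() if "Amide" not in k) == 0

    def test_donor_and_acceptor_maps_have_no_internal_overlap(self):
        # each atom maps to at most one donor group and one acceptor group
        assert len(DONOR_GROUP_MAP) == len(set(DONOR_GROUP_MAP))
        assert len(ACCEPTOR_GROUP_MAP) == len(set(ACCEPTOR_GROUP_MAP))
        # lysine NZ sits only in the positively charged donor group
        assert DONOR_GROUP_MAP[("LYS", "NZ")] == "PD(K+R+HIP)"
        assert ("LYS", "NZ") not in ACCEPTOR_GROUP_MAP

    def test_group_sums_equal_total_flagged_atoms(self, mixed_pocket_complex):
        protein, _lig, exp = mixed_pocket_complex
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_pocket(protein, np.asarray(exp["center"]), exp["maxD"])
            raw = residue_group_descriptors(sel)
        n_donor_atoms = 0
        n_acceptor_atoms = 0
        for res, atom_name, element, _xyz in sel.atoms_hb:
            if element.upper() == "H":
                continue
            if (atom_name == "N" and res.name != "PRO") or \
                    (res.name, atom_name) in DONOR_GROUP_MAP:
                n_donor_atoms += 1
            if atom_name == "O" or (res.name, atom_name) in ACCEPTOR_GROUP_MAP:
                n_acceptor_atoms += 1
        assert sum(v for k, v in raw.items() if k.startswith("PD(")) == n_donor_atoms
        assert sum(v for k, v in raw.items() if k.startswith("PA(")) == n_acceptor_atoms


class TestVolume:
    def test_empty_sphere_matches_analytic(self):
        far = ProteinStructure([_point_residue("GLY", "N", "N", 100.0)])
        v = pocket_volume(far, CENTER, 2.5, grid=0.25)
        assert v == pytest.approx(oracle_sphere_volume(2.5), rel=0.02)

    def test_buried_sphere_is_zero(self):
        ax = np.arange(-4, 4.5, 1.5)
        atoms = [("C", "C", np.array([x, y, z]))
                 for x in ax for y in ax for z in ax]
        slab = ProteinStructure([Residue("GLY", "A", 1, atoms)])
        assert pocket_volume(slab, CENTER, 2.5, grid=0.25) == 0.0

    def test_half_space_wall_gives_half_sphere(self):
        # exclusion surface (atom plane + vdW 1.70 + probe 1.40) bisects the
        # sphere between two grid planes, avoiding boundary ties
        maxd = 2.5
        ax = np.arange(-4.0, 4.01, 0.25)
        atoms = [("C", "C", np.array([x, y, -3.15]))
                 for x in ax for y in ax]
        wall = ProteinStructure([Residue("GLY", "A", 1, atoms)])
        v = pocket_volume(wall, CENTER, maxd, grid=0.1)
        assert v == pytest.approx(oracle_sphere_volume(maxd) / 2, rel=0.05)

    def test_grid_convergence(self):
        far = ProteinStructure([_point_residue("GLY", "N", "N", 100.0)])
        v1 = pocket_volume(far, CENTER, 3.0, grid=0.5)
        v2 = pocket_volume(far, CENTER, 3.0, grid=0.25)
        assert abs(v1 - v2) / v2 < 0.05

    def test_nonpositive_grid_rejected(self):
        far = ProteinStructure([_point_residue("GLY", "N", "N", 100.0)])
        with pytest.raises(ValueError):
            pocket_volume(far, CENTER, 3.0, grid=0.0)


class TestDescriptorVector:
    def test_exactly_fourteen_features(self, glycine_complex):
        protein, _lig, exp = glycine_complex
        desc = pocket_descriptors(protein, np.asarray(exp["center"]), exp["maxD"])
        assert tuple(desc.as_dict()) == POCKET_FEATURE_NAMES
        assert len(desc.as_dict()) == 14

    def test_counts_scaled_by_maxd_pvol_unscaled(self, glycine_complex):
        protein, _lig, exp = glycine_complex
        maxd = exp["maxD"]
        desc = pocket_descriptors(protein, np.asarray(exp["center"]), maxd)
        assert desc["PD(Amide-NH)"] == pytest.approx(1.0 / maxd)
        assert desc["PA(Amide-O)"] == pytest.approx(1.0 / maxd)
        assert desc["PVol"] > 1.0  # cubic Angstrom, not a per-Angstrom count

    def test_doubling_maxd_in_empty_environment_scales_pvol_eightfold(self):
        far = ProteinStructure([_point_residue("GLY", "N", "N", 200.0)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d1 = pocket_descriptors(far, CENTER, 3.0, grid=0.2)
            d2 = pocket_descriptors(far, CENTER, 6.0, grid=0.2)
        for name in POCKET_FEATURE_NAMES[:-1]:
            assert d1[name] == 0 and d2[name] == 0
        assert d2["PVol"] == pytest.approx(8 * d1["PVol"], rel=0.02)

    def test_translation_invariance(self, aspartate_complex):
        protein, _lig, exp = aspartate_complex
        center = np.asarray(exp["center"])
        shift = np.array([11.0, -3.0, 7.0])
        d0 = pocket_descriptors(protein, center, exp["maxD"])
        d1 = pocket_descriptors(protein.translated(shift), center + shift,
                                exp["maxD"])
        for name in POCKET_FEATURE_NAMES:
            assert d0[name] == pytest.approx(d1[name], abs=1e-9)

    def test_pose_invariance_depends_only_on_maxd_and_center(self,
                                                             aspartate_complex):
        """Two conformers with equal maxD yield identical pocket descriptors."""
        from raspdplus.ligand_features import max_distance

        protein, lig, exp = aspartate_complex
        center = np.asarray(exp["center"])
        theta = 1.1
        rot = np.array(
            [[math.cos(theta), -math.sin(theta), 0],
             [math.sin(theta), math.cos(theta), 0],
             [0, 0, 1]]
        )
        conformer_b = MolecularGraph(
            atoms=[(el, rot @ xyz + 20.0, c, ar) for el, xyz, c, ar in lig.atoms],
            bonds=lig.bonds, name=lig.name,
        )
        maxd_a, maxd_b = max_distance(lig), max_distance(conformer_b)
        assert maxd_a == pytest.approx(maxd_b, abs=1e-9)
        d_a = pocket_descriptors(protein, center, maxd_a)
        d_b = pocket_descriptors(protein, center, maxd_b)
        assert d_a.as_dict() == pytest.approx(d_b.as_dict(), abs=1e-12)


class TestCofactorFlag:
    def test_hetero_atom_in_sphere_flags(self):
        prot = ProteinStructure(
            [_point_residue("GLY", "N", "N", 3.0)],
            [Residue("HEM", "A", 90, [("FE", "Fe", np.array([1.0, 0, 0]))],
                     hetero=True)],
        )
        assert cofactor_in_pocket(prot, CENTER, 4.0) is True

    def test_water_ignored(self):
        prot = ProteinStructure(
            [_point_residue("GLY", "N", "N", 3.0)],
            [Residue("HOH", "A", 90, [("O", "O", np.array([1.0, 0, 0]))],
                     hetero=True)],
        )
        assert cofactor_in_pocket(prot, CENTER, 4.0) is False
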