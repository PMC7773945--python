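"""Structure I/O, metal filtering, and affinity conversion."""

from __future__ import annotations

import math
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raspdplus.structio import (
    ComplexRecord,
    MolecularGraph,
    ProteinStructure,
    Residue,
    affinity_to_dG,
    filter_metal_contacts,
    mol_from_smiles,
    read_affinity_table,
    read_ligand,
    read_ligands,
    read_protein,
    write_ligand_sdf,
    write_protein_pdb,
)
from raspdplus.synthdata import FIXTURE_SMILES, fixture_ligand


def _pdb_line(rec, serial, name, resname, chain, num, xyz, occ=1.0,
              altloc=" ", element="C"):
    return (
        f"{rec:<6s}{serial:5d} {name:<4s}{altloc}{resname:<3s} {chain}"
        f"{num:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{occ:6.2f}{0.0:6.2f}          {element:>2s}\n"
    )


class TestReadProtein:
    def test_minimal_residue_roundtrip(self, tmp_path):
        text = (
            _pdb_line("ATOM", 1, "N", "GLY", "A", 1, (0, 0, 0), element="N")
            + _pdb_line("ATOM", 2, "CA", "GLY", "A", 1, (1.5, 0, 0))
            + _pdb_line("ATOM", 3, "C", "GLY", "A", 1, (2.2, 1.3, 0))
        )
        p = tmp_path / "mini.pdb"
        p.write_text(text)
        prot = read_protein(p)
        assert len(prot.residues) == 1
        assert len(prot.residues[0].atoms) == 3
        assert prot.residues[0].name == "GLY"

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        text = (
            _pdb_line("ATOM", 1, "CA", "ALA", "A", 1, (0, 0, 0), occ=0.6,
                      altloc="A")
            + _pdb_line("ATOM", 2, "CA", "ALA", "A", 1, (5, 0, 0), occ=0.4,
                        altloc="B")
        )
        p = tmp_path / "alt.pdb"
        p.write_text(text)
        prot = read_protein(p)
        (atom,) = prot.residues[0].atoms
        assert np.allclose(atom[2], [0, 0, 0])  # conformer A retained

    def test_altloc_occupancy_tie_breaks_alphabetically(self, tmp_path):
        text = (
            _pdb_line("ATOM", 1, "CA", "ALA", "A", 1, (5, 0, 0), occ=0.5,
                      altloc="B")
            + _pdb_line("ATOM", 2, "CA", "ALA", "A", 1, (0, 0, 0), occ=0.5,
                        altloc="A")
        )
        p = tmp_path / "tie.pdb"
        p.write_text(text)
        prot = read_protein(p)
        (atom,) = prot.residues[0].atoms
        assert np.allclose(atom[2], [0, 0, 0])

    def test_remark_only_file_raises_no_atoms(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("REMARK nothing here\nREMARK still nothing\n")
        with pytest.raises(ValueError, match="no atoms"):
            read_protein(p)

    def test_roundtrip_preserves_atoms_and_coordinates(self, tmp_path,
                                                       glycine_complex):
        protein, _lig, _exp = glycine_complex
        out = tmp_path / "rt.pdb"
        write_protein_pdb(protein, out)
        back = read_protein(out)
        orig = sorted(
            (r.name, a[0], a[1]) for r in protein.residues for a in r.atoms
        )
        got = sorted((r.name, a[0], a[1]) for r in back.residues for a in r.atoms)
        assert orig == got
        a0 = protein.atom_coordinates()
        a1 = back.atom_coordinates()
        assert np.allclose(np.sort(a0, axis=0), np.sort(a1, axis=0), atol=1e-3)


class TestReadLigand:
    def test_sdf_ethanol_graph(self, tmp_path):
        mol = fixture_ligand("ethanol")
        p = tmp_path / "ethanol.sdf"
        write_ligand_sdf([mol], p)
        back = read_ligand(p)
        assert len(back.heavy_indices()) == 3
        heavy = set(back.heavy_indices())
        heavy_bonds = [b for b in back.bonds if b[0] in heavy and b[1] in heavy]
        assert len(heavy_bonds) == 2

    def test_smiles_benzene_aromatic(self):
        mol = mol_from_smiles("c1ccccc1")
        assert sum(1 for el, _, _, ar in mol.atoms if ar and el == "C") == 6
        assert len(mol.bonds) == 6

    def test_smiles_embedding_is_deterministic(self):
        a = mol_from_smiles("CCO", embed3d=True)
        b = mol_from_smiles("CCO", embed3d=True)
        assert np.allclose(a.coordinates, b.coordinates)

    @pytest.mark.parametrize(
        "name", ["ethanol", "benzene", "acetamide", "aspirin", "morpholine"]
    )
    def test_mol2_and_sdf_give_identical_heavy_graphs(self, tmp_path, name):
        if shutil.which("obabel") is None:
            pytest.skip("openbabel CLI not available for MOL2 conversion")
        mol = fixture_ligand(name)
        sdf = tmp_path / f"{name}.sdf"
        mol2 = tmp_path / f"{name}.mol2"
        write_ligand_sdf([mol], sdf)
        subprocess.run(["obabel", str(sdf), "-O", str(mol2)], check=True,
                       capture_output=True)
        from_sdf = read_ligand(sdf)
        from_mol2 = read_ligand(mol2)

        def heavy_graph(g):
            heavy = g.heavy_indices()
            pos = {h: k for k, h in enumerate(heavy)}
            elements = sorted(g.elements[h] for h in heavy)
            edges = sorted(
                (min(pos[i], pos[j]), max(pos[i], pos[j]))
                for i, j, _ in g.bonds if i in pos and j in pos
            )
            return elements, len(edges)

        assert heavy_graph(from_sdf) == heavy_graph(from_mol2)

    def test_empty_sdf_raises(self, tmp_path):
        p = tmp_path / "nothing.sdf"
        p.write_text("")
        with pytest.raises(ValueError):
            read_ligands(p)


def _complex_with_metal(metal_distance: float | None, element="Zn"):
    lig = MolecularGraph(
        atoms=[("C", np.zeros(3), 0, False), ("C", np.array([1.5, 0, 0]), 0, False)],
        bonds=[(0, 1, 1.0)],
        name="lig",
    )
    residues = [Residue("GLY", "A", 1, [("CA", "C", np.array([10.0, 0, 0]))])]
    hetero = []
    if metal_distance is not None:
        hetero = [Residue(element.upper(), "A", 90,
                          [(element.upper(), element, np.array([0.0, 0, metal_distance]))],
                          hetero=True)]
    prot = ProteinStructure(residues, hetero)
    return ComplexRecord(prot, lig, "test", dG=-7.0)


class TestMetalFilter:
    def test_metal_inside_cutoff_discards(self):
        assert filter_metal_contacts(_complex_with_metal(2.0)) is False

    def test_metal_outside_cutoff_keeps(self):
        assert filter_metal_contacts(_complex_with_metal(2.2)) is True

    def test_no_metals_keeps(self):
        assert filter_metal_contacts(_complex_with_metal(None)) is True

    def test_nonmetal_hetero_ignored(self):
        assert filter_metal_contacts(_complex_with_metal(1.0, element="O")) is True

    def test_invariant_to_joint_rigid_translation(self):
        rec = _complex_with_metal(2.0)
        shift = np.array([13.0, -4.0, 2.5])
        lig = MolecularGraph(
            atoms=[(el, xyz + shift, c, ar) for el, xyz, c, ar in rec.ligand.atoms],
            bonds=rec.ligand.bonds,
        )
        moved = ComplexRecord(rec.protein.translated(shift), lig, "t", dG=-7.0)
        assert filter_metal_contacts(moved) == filter_metal_contacts(rec)


class TestAffinityConversion:
    def test_one_molar_is_zero(self):
        assert affinity_to_dG(1.0) == 0.0

    def test_nanomolar_spot_value(self):
        # hand evaluation of R*T*ln(1e-9) with R = 1.9872e-3, T = 298.15
        expected = -1.9872e-3 * 298.15 * 9 * math.log(10)
        assert abs(affinity_to_dG(1e-9) - expected) < 1e-12
        assert abs(expected - (-12.278)) < 1e-3

    def test_monotone_in_K_and_types_identical(self):
        ks = [1e-12, 1e-9, 1e-6, 1e-3, 1.0, 10.0]
        vals = [affinity_to_dG(k) for k in ks]
        assert vals == sorted(vals)
        for k in (1e-9, 1e-4):
            assert affinity_to_dG(k, "Kd") == affinity_to_dG(k, "Ki")
            assert affinity_to_dG(k, "Ki") == affinity_to_dG(k, "IC50")

    @pytest.mark.parametrize("bad", [0.0, -1e-9])
    def test_nonpositive_raises(self, bad):
        with pytest.raises(ValueError):
            affinity_to_dG(bad)

    @settings(derandomize=True, deadline=None)
    @given(
        k=st.floats(min_value=1e-14, max_value=1e3),
        scale=st.floats(min_value=1.001, max_value=1e6),
        t=st.floats(min_value=200.0, max_value=400.0),
    )
    def test_order_and_temperature_linearity_properties(self, k, scale, t):
        # stronger binding (smaller K) is always more favorable, and
        # dG is linear in T at fixed K
        assert affinity_to_dG(k) < affinity_to_dG(k * scale)
        assert affinity_to_dG(k, temperature=t) == pytest.approx(
            t / 298.15 * affinity_to_dG(k), rel=1e-12)


class TestAffinityTable:
    def test_units_converted_and_precedence(self, tmp_path):
        p = tmp_path / "aff.csv"
        p.write_text(
            "id,value,unit,type\n"
            "a,5,nM,Kd\n"
            "b,2,uM,IC50\n"
            "b,10,uM,Ki\n"  # Ki beats IC50 despite larger value
            "c,1,mM,Ki\n"
        )
        table = read_affinity_table(p)
        assert table["a"][0] == pytest.approx(5e-9) and table["a"][1] == "Kd"
        assert table["b"][0] == pytest.approx(1e-5) and table["b"][1] == "Ki"
        assert table["c"][0] == pytest.approx(1e-3) and table["c"][1] == "Ki"
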