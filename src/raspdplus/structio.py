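"""Structure and affinity I/O, complex assembly, and dataset filters.

Proteins are read from PDB files, ligands from SDF/MOL2/PDB/SMILES.  The
module also converts experimental affinities (Kd, Ki, IC50, in molar units)
to binding free energies and applies the metal-contact filter used to keep
metal-coordinated complexes out of training data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

__all__ = [
    "MolecularGraph",
    "ProteinStructure",
    "Residue",
    "ComplexRecord",
    "read_protein",
    "read_ligand",
    "write_protein_pdb",
    "write_ligand_sdf",
    "filter_metal_contacts",
    "affinity_to_dG",
    "read_affinity_table",
    "GAS_CONSTANT_KCAL",
    "DEFAULT_METALS",
]

#: Gas constant in kcal/(mol K).
GAS_CONSTANT_KCAL = 1.9872e-3

#: Biologically common metals found as PDB heteroatoms.
DEFAULT_METALS = frozenset(
    {"LI", "NA", "K", "MG", "CA", "MN", "FE", "CO", "NI", "CU", "ZN", "CD", "HG"}
)

#: Seed for deterministic 3D embedding of SMILES inputs (maxD reproducibility).
EMBED_SEED = 20201217


@dataclass
class MolecularGraph:
    """A small molecule: elements, coordinates, bonds, aromaticity.

    ``atoms`` holds ``(element, xyz, formal_charge, aromatic)`` tuples with
    coordinates in Angstrom (``xyz`` may be None for connectivity-only
    inputs); ``bonds`` holds undirected ``(i, j, order)`` triples stored once
    with ``i < j``.
    """

    atoms: list[tuple[str, np.ndarray | None, int, bool]]
    bonds: list[tuple[int, int, float]]
    name: str = ""
    _rdkit: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if n == 0:
            raise ValueError("empty molecule")
        if not any(el.upper() != "H" for el, *_ in self.atoms):
            raise ValueError("molecule has no heavy atoms")
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond ({i}, {j}) for {n} atoms")
        for el, xyz, _, _ in self.atoms:
            if xyz is not None and not np.all(np.isfinite(xyz)):
                raise ValueError("non-finite atom coordinates")

    # -- convenience views -------------------------------------------------
    @property
    def elements(self) -> list[str]:
        return [el for el, *_ in self.atoms]

    @property
    def coordinates(self) -> np.ndarray:
        """(n, 3) coordinate array; raises if any atom lacks coordinates."""
        coords = [xyz for _, xyz, _, _ in self.atoms]
        if any(c is None for c in coords):
            raise ValueError(f"molecule {self.name!r} has atoms without coordinates")
        return np.asarray(coords, dtype=float)

    @property
    def has_coordinates(self) -> bool:
        return all(xyz is not None for _, xyz, _, _ in self.atoms)

    def heavy_indices(self) -> list[int]:
        return [i for i, (el, *_rest) in enumerate(self.atoms) if el.upper() != "H"]

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, name: str = "") -> "MolecularGraph":
        if mol is None or mol.GetNumAtoms() == 0:
            raise ValueError("empty molecule")
        conf = mol.GetConformer() if mol.GetNumConformers() else None
        atoms = []
        for atom in mol.GetAtoms():
            xyz = None
            if conf is not None:
                p = conf.GetAtomPosition(atom.GetIdx())
                xyz = np.array([p.x, p.y, p.z], dtype=float)
            atoms.append(
                (atom.GetSymbol(), xyz, atom.GetFormalCharge(), atom.GetIsAromatic())
            )
        bonds = []
        for bond in mol.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            bonds.append((min(i, j), max(i, j), bond.GetBondTypeAsDouble()))
        return cls(atoms=atoms, bonds=sorted(bonds), name=name or mol.GetProp("_Name")
                   if mol.HasProp("_Name") else name, _rdkit=mol)

    def to_rdkit(self) -> Chem.Mol:
        """RDKit molecule; rebuilt from the graph when no original is cached."""
        if self._rdkit is not None:
            return self._rdkit
        rw = Chem.RWMol()
        for el, _, charge, aromatic in self.atoms:
            a = Chem.Atom(el)
            a.SetFormalCharge(charge)
            a.SetIsAromatic(aromatic)
            rw.AddAtom(a)
        order_map = {
            1.0: Chem.BondType.SINGLE,
            1.5: Chem.BondType.AROMATIC,
            2.0: Chem.BondType.DOUBLE,
            3.0: Chem.BondType.TRIPLE,
        }
        for i, j, order in self.bonds:
            rw.AddBond(i, j, order_map.get(order, Chem.BondType.SINGLE))
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        if self.has_coordinates:
            conf = Chem.Conformer(mol.GetNumAtoms())
            for idx, (_, xyz, _, _) in enumerate(self.atoms):
                conf.SetAtomPosition(idx, [float(v) for v in xyz])
            mol.AddConformer(conf, assignId=True)
        self._rdkit = mol
        return mol


@dataclass
class Residue:
    """One residue: 3-letter name, chain, number, and named atoms."""

    name: str
    chain: str
    number: int
    atoms: list[tuple[str, str, np.ndarray]]  # (atom name, element, xyz)
    hetero: bool = False

    def center_of_mass(self) -> np.ndarray:
        """Mass-weighted center over the atoms present in the record."""
        masses = np.array([_atomic_mass(el) for _, el, _ in self.atoms])
        coords = np.array([xyz for _, _, xyz in self.atoms])
        return (masses[:, None] * coords).sum(axis=0) / masses.sum()


@dataclass
class ProteinStructure:
    """A protein: polymer residues plus flagged hetero records."""

    residues: list[Residue]
    hetero: list[Residue] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        if not self.residues and not self.hetero:
            raise ValueError("no atoms: empty structure")
        seen: set[tuple[str, int]] = set()
        for res in self.residues:
            key = (res.chain, res.number)
            if key in seen:
                raise ValueError(f"duplicate residue number {key}")
            seen.add(key)

    def polymer_atoms(self) -> Iterator[tuple[Residue, str, str, np.ndarray]]:
        for res in self.residues:
            for atom_name, element, xyz in res.atoms:
                yield res, atom_name, element, xyz

    def atom_coordinates(self, heavy_only: bool = False) -> np.ndarray:
        coords = [
            xyz
            for _, _, el, xyz in self.polymer_atoms()
            if not (heavy_only and el.upper() == "H")
        ]
        return np.asarray(coords, dtype=float).reshape(-1, 3)

    def translated(self, shift: Sequence[float]) -> "ProteinStructure":
        shift = np.asarray(shift, dtype=float)

        def _move(res: Residue) -> Residue:
            return Residue(
                res.name, res.chain, res.number,
                [(n, e, xyz + shift) for n, e, xyz in res.atoms], res.hetero,
            )

        return ProteinStructure(
            [_move(r) for r in self.residues],
            [_move(r) for r in self.hetero],
            self.name,
        )


@dataclass
class ComplexRecord:
    """A protein-ligand complex with an optional affinity or free energy."""

    protein: ProteinStructure
    ligand: MolecularGraph
    id: str
    affinity: tuple[float, str] | None = None  # (molar concentration, Kd|Ki|IC50)
    dG: float | None = None

    def __post_init__(self) -> None:
        if self.dG is None and self.affinity is not None:
            value, kind = self.affinity
            self.dG = affinity_to_dG(value, kind)
        if self.dG is not None and not math.isfinite(self.dG):
            raise ValueError("non-finite dG")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _atomic_mass(element: str) -> float:
    pt = Chem.GetPeriodicTable()
    try:
        return pt.GetAtomicWeight(element.capitalize())
    except Exception as exc:  # pragma: no cover - rdkit raises RuntimeError
        raise ValueError(f"unknown element {element!r}") from exc


def _guess_element(atom_name: str) -> str:
    """Element from a PDB atom name when columns 77-78 are blank."""
    stripped = atom_name.strip()
    if stripped[:2].upper() in {"CL", "BR", "FE", "ZN", "MG", "MN", "NA", "CA"} and len(
        stripped
    ) <= 2:
        return stripped.capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def read_protein(path: str | Path, format: str = "PDB") -> ProteinStructure:
    """Read a protein from a PDB file (Biopython-backed).

    All ATOM records are kept; HETATM records are retained with a hetero
    flag.  Alternate locations are resolved to the highest-occupancy
    conformer (ties broken alphabetically by altLoc id).  Only the first
    MODEL of a multi-model file is read.
    """
    if format.upper() != "PDB":
        raise ValueError(f"unsupported protein format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))

    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    try:
        structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise ValueError(f"{path.name}: cannot parse PDB: {exc}") from exc

    models = list(structure)
    if not models:
        raise ValueError(f"{path.name}: no atoms")

    polymer: list[Residue] = []
    het: list[Residue] = []
    n_atoms = 0
    for chain in models[0]:
        for bio_res in chain:
            hetflag, resseq, _icode = bio_res.id
            hetero = hetflag.strip() != ""
            atoms: list[tuple[str, str, np.ndarray]] = []
            for atom in bio_res:
                if atom.is_disordered():
                    # highest occupancy wins; ties break on altLoc id
                    atom = sorted(
                        atom.disordered_get_list(),
                        key=lambda a: (-(a.get_occupancy() or 0.0),
                                       a.get_altloc()),
                    )[0]
                element = (atom.element or "").strip() or _guess_element(
                    atom.get_name())
                atoms.append((atom.get_name(), element.capitalize(),
                              np.asarray(atom.get_coord(), dtype=float)))
            if not atoms:
                continue
            n_atoms += len(atoms)
            res = Residue(bio_res.get_resname().strip(), chain.id, resseq,
                          atoms, hetero=hetero)
            (het if hetero else polymer).append(res)

    if n_atoms == 0:
        raise ValueError(f"{path.name}: no atoms")
    return ProteinStructure(polymer, het, name=path.stem)


def write_protein_pdb(protein: ProteinStructure, path: str | Path) -> None:
    """Write a ProteinStructure back out as a PDB file."""
    serial = 0
    with open(path, "w") as fh:
        for res in list(protein.residues) + list(protein.hetero):
            rec = "HETATM" if res.hetero else "ATOM  "
            for atom_name, element, xyz in res.atoms:
                serial += 1
                name = atom_name if len(atom_name) == 4 else f" {atom_name:<3s}"
                fh.write(
                    f"{rec}{serial:5d} {name:<4.4s} {res.name:<3s} {res.chain}"
                    f"{res.number:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.0:6.2f}{0.0:6.2f}          {element.upper():>2s}\n"
                )
        fh.write("END\n")


def _read_smiles_line_file(path: Path) -> list[Chem.Mol]:
    mols = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            mol = Chem.MolFromSmiles(parts[0])
            if mol is None:
                raise ValueError(f"{path.name}: bad SMILES on line {lineno}")
            mol.SetProp("_Name", parts[1].strip() if len(parts) > 1 else f"mol{lineno}")
            mols.append(mol)
    return mols


def mol_from_smiles(smiles: str, name: str = "", embed3d: bool = False) -> MolecularGraph:
    """Build a MolecularGraph from SMILES.

    With ``embed3d`` a single conformer is generated with a fixed ETKDG seed
    so the geometric descriptor maxD is reproducible run to run.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES {smiles!r}")
    if embed3d:
        mol = Chem.AddHs(mol)
        params = AllChem.ETKDGv3()
        params.randomSeed = EMBED_SEED
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise ValueError(f"3D embedding failed for {smiles!r}")
    return MolecularGraph.from_rdkit(mol, name=name)


def read_ligand(path: str | Path, format: str | None = None) -> MolecularGraph:
    """Read a single ligand from SDF, MOL2, PDB, or a SMILES line file."""
    mols = read_ligands(path, format=format)
    return mols[0]


def read_ligands(path: str | Path, format: str | None = None) -> list[MolecularGraph]:
    """Read all ligands from a file; format inferred from the suffix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "sdf":
        try:
            supplier = Chem.SDMolSupplier(str(path), removeHs=False)
            mols = [m for m in supplier if m is not None]
        except OSError as exc:
            raise ValueError(f"{path.name}: cannot read SDF: {exc}") from exc
    elif fmt == "mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False)
        mols = [mol] if mol is not None else []
    elif fmt == "pdb":
        mol = Chem.MolFromPDBFile(str(path), removeHs=False)
        mols = [mol] if mol is not None else []
    elif fmt in ("smi", "smiles", "txt"):
        raw = _read_smiles_line_file(path)
        return [MolecularGraph.from_rdkit(m) for m in raw]
    else:
        raise ValueError(f"unsupported ligand format {fmt!r}")
    if not mols:
        raise ValueError(f"{path.name}: no valid molecules")
    return [MolecularGraph.from_rdkit(m) for m in mols]


def write_ligand_sdf(mols: Iterable[MolecularGraph], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for graph in mols:
        mol = graph.to_rdkit()
        mol.SetProp("_Name", graph.name)
        writer.write(mol)
    writer.close()


# ---------------------------------------------------------------------------
# filters and conversions
# ---------------------------------------------------------------------------

def filter_metal_contacts(
    record: ComplexRecord,
    cutoff: float = 2.1,
    metals: frozenset[str] | set[str] = DEFAULT_METALS,
) -> bool:
    """True = keep the complex; False = discard (a metal coordinates the ligand).

    A complex is discarded when any hetero atom whose element is in
    ``metals`` lies strictly within ``cutoff`` Angstrom of any ligand atom.
    """
    lig_coords = record.ligand.coordinates
    metals = {m.upper() for m in metals}
    for res in record.protein.hetero:
        for _, element, xyz in res.atoms:
            if element.upper() not in metals:
                continue
            d = np.linalg.norm(lig_coords - xyz[None, :], axis=1)
            if np.min(d) < cutoff:
                return False
    return True


def affinity_to_dG(value: float, kind: str = "Kd", temperature: float = 298.15) -> float:
    """Binding free energy (kcal/mol) from a molar affinity constant.

    dG = R T ln K with K the dissociation/inhibition constant or IC50 in
    molar units, so sub-molar affinities (e.g. nanomolar binders) map to
    negative, favorable free energies.  All three affinity types are treated
    identically.
    """
    if kind not in ("Kd", "Ki", "IC50"):
        raise ValueError(f"unknown affinity type {kind!r}")
    if not (value > 0):
        raise ValueError(f"affinity must be positive, got {value}")
    return GAS_CONSTANT_KCAL * temperature * math.log(value)


_UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}
_AFFINITY_PRECEDENCE = {"Kd": 0, "Ki": 1, "IC50": 2}


def read_affinity_table(path: str | Path) -> dict[str, tuple[float, str]]:
    """Read a CSV of affinities (columns: id, value, unit, type) in molar units.

    When one id carries several measurements the most thermodynamically
    direct wins: Kd over Ki over IC50; within a type the lower value wins.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"id", "value", "unit", "type"}
    if not required.issubset(df.columns):
        raise ValueError(f"affinity table must have columns {sorted(required)}")
    out: dict[str, tuple[float, str]] = {}
    for _, row in df.iterrows():
        unit = str(row["unit"])
        if unit not in _UNIT_FACTORS:
            raise ValueError(f"unknown unit {unit!r}")
        kind = str(row["type"])
        if kind not in _AFFINITY_PRECEDENCE:
            raise ValueError(f"unknown affinity type {kind!r}")
        molar = float(row["value"]) * _UNIT_FACTORS[unit]
        key = str(row["id"])
        if key in out:
            old_molar, old_kind = out[key]
            if (_AFFINITY_PRECEDENCE[kind], molar) >= (
                _AFFINITY_PRECEDENCE[old_kind], old_molar
            ):
                continue
        out[key] = (molar, kind)
    return out
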