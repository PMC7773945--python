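"""The six ligand descriptors plus the pocket-sizing radius maxD.

Descriptors: molecular weight (MASS), hydrogen-bond donor and acceptor atom
counts (D, A), Wildman-Crippen logP and molar refractivity (MR), and the
Wiener topological index (W).  maxD -- the largest distance from any ligand
atom to the ligand center of mass -- is not itself a model feature but sets
the radius of the spheres used to select the protein binding pocket.

Donor/acceptor rule set (fixed, documented):
  * donors:    N or O atoms bearing at least one hydrogen (explicit or
               implicit); the donor *atom* is counted, not its hydrogens.
  * acceptors: all N and O atoms except (a) the nitrogen and oxygens of
               nitro groups and (b) aromatic N-H nitrogens (pyrrole-type,
               lone pair in the ring pi system).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from raspdplus.structio import MolecularGraph, _atomic_mass

__all__ = [
    "LigandDescriptors",
    "molecular_weight",
    "hbond_counts",
    "crippen_contributions",
    "wiener_index",
    "max_distance",
    "ligand_descriptors",
    "strip_salts",
    "LIGAND_FEATURE_NAMES",
]

LIGAND_FEATURE_NAMES = ("MASS", "D", "A", "logP", "MR", "W")


@dataclass(frozen=True)
class LigandDescriptors:
    """The six ligand features; maxD is carried separately."""

    MASS: float  # g/mol
    D: int  # H-bond donor atoms
    A: int  # H-bond acceptor atoms
    logP: float  # Wildman-Crippen octanol/water partition coefficient
    MR: float  # Wildman-Crippen molar refractivity, cm^3/mol
    W: int  # Wiener index on the heavy-atom graph
    maxD: float | None = None  # Angstrom; None for coordinate-free inputs

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in LIGAND_FEATURE_NAMES}


def molecular_weight(mol: MolecularGraph) -> float:
    """Average molecular weight in g/mol, implicit hydrogens included."""
    return float(Descriptors.MolWt(mol.to_rdkit()))


# Nitro group in either charge-separated or hypervalent notation.
_NITRO = Chem.MolFromSmarts("[$([NX3](=O)=O),$([NX3+](=O)[O-])]([!#8])")


def hbond_counts(mol: MolecularGraph) -> tuple[int, int]:
    """(donor atom count, acceptor atom count) under the module rule set."""
    rdmol = mol.to_rdkit()
    nitro_atoms: set[int] = set()
    for match in rdmol.GetSubstructMatches(_NITRO):
        n_idx = match[0]
        nitro_atoms.add(n_idx)
        for nbr in rdmol.GetAtomWithIdx(n_idx).GetNeighbors():
            if nbr.GetSymbol() == "O":
                nitro_atoms.add(nbr.GetIdx())
    donors = acceptors = 0
    for atom in rdmol.GetAtoms():
        if atom.GetSymbol() not in ("N", "O"):
            continue
        has_h = atom.GetTotalNumHs(includeNeighbors=True) > 0
        if has_h:
            donors += 1
        if atom.GetIdx() in nitro_atoms:
            continue
        if atom.GetSymbol() == "N" and atom.GetIsAromatic() and has_h:
            continue  # pyrrole-type N: lone pair delocalized into the ring
        acceptors += 1
    return donors, acceptors


def crippen_contributions(mol: MolecularGraph) -> tuple[float, float]:
    """(logP, MR) as sums of Wildman-Crippen atomic contributions."""
    rdmol = mol.to_rdkit()
    if rdmol.GetNumAtoms() == 0:
        raise ValueError("empty molecule")
    return float(Crippen.MolLogP(rdmol)), float(Crippen.MolMR(rdmol))


def wiener_index(mol: MolecularGraph) -> int:
    """Sum of shortest-path bond distances over all heavy-atom pairs.

    Hydrogens are excluded so the index does not depend on whether a
    structure was prepared with explicit hydrogens.  For a disconnected
    heavy-atom graph the sum runs within components and a warning is issued.
    """
    heavy = mol.heavy_indices()
    n = len(heavy)
    if n <= 1:
        return 0
    pos = {orig: k for k, orig in enumerate(heavy)}
    rows, cols = [], []
    for i, j, _ in mol.bonds:
        if i in pos and j in pos:
            rows += [pos[i], pos[j]]
            cols += [pos[j], pos[i]]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    dist = shortest_path(adj, method="BF", unweighted=True, directed=False)
    finite = np.isfinite(dist)
    if not finite.all():
        warnings.warn(
            "disconnected heavy-atom graph: Wiener index summed within components",
            stacklevel=2,
        )
    return int(round(dist[finite].sum() / 2))


def max_distance(mol: MolecularGraph) -> float:
    """maxD: largest atom distance from the mass-weighted center of mass (A)."""
    coords = mol.coordinates
    masses = np.array([_atomic_mass(el) for el in mol.elements])
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    return float(np.linalg.norm(coords - com[None, :], axis=1).max())


def strip_salts(mol: MolecularGraph) -> MolecularGraph:
    """Keep the largest covalent fragment (by heavy-atom count, then mass).

    Screening libraries carry counter-ions; descriptors are computed on the
    parent molecule only.
    """
    rdmol = mol.to_rdkit()
    frags = Chem.GetMolFrags(rdmol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return mol
    best = max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Descriptors.MolWt(f)))
    return MolecularGraph.from_rdkit(best, name=mol.name)


def ligand_descriptors(mol: MolecularGraph, salt_strip: bool = True) -> LigandDescriptors:
    """Compute all six ligand descriptors (and maxD when coordinates exist)."""
    if salt_strip:
        mol = strip_salts(mol)
    donors, acceptors = hbond_counts(mol)
    logp, mr = crippen_contributions(mol)
    return LigandDescriptors(
        MASS=molecular_weight(mol),
        D=donors,
        A=acceptors,
        logP=logp,
        MR=mr,
        W=wiener_index(mol),
        maxD=max_distance(mol) if mol.has_coordinates else None,
    )
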