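"""Binding-pocket selection and the fourteen protein descriptors.

A sphere is centered on a known or assumed binding-site position.  Residues
whose mass-weighted center of mass lies within ``maxD + 0.9`` Angstrom of
the center contribute Wildman-Crippen logP and molar refractivity sums,
split between aromatic (PHE/TRP/TYR/HIS) and non-aromatic residues.  Protein
atoms within ``maxD + 3.0`` Angstrom contribute hydrogen-bond donor and
acceptor counts, partitioned into backbone and residue-group features by a
fixed atom-name mapping table.  The thirteen residue-derived values are
divided by the ligand maxD (size normalization); the pocket volume PVol is
reported unscaled.

Because only ``maxD`` and the center enter the selection, the descriptors
are invariant to the ligand's pose and conformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors
from scipy.spatial import cKDTree

from raspdplus.structio import ProteinStructure, Residue

__all__ = [
    "PocketSelection",
    "PocketDescriptors",
    "select_pocket",
    "residue_group_descriptors",
    "pocket_volume",
    "pocket_descriptors",
    "cofactor_in_pocket",
    "POCKET_FEATURE_NAMES",
    "AROMATIC_RESIDUES",
    "DONOR_GROUP_MAP",
    "ACCEPTOR_GROUP_MAP",
]

#: Canonical order of the fourteen pocket features.
POCKET_FEATURE_NAMES = (
    "PMR(Arom)",
    "PMR(Non-Arom)",
    "PlogP(Arom)",
    "PlogP(Non-Arom)",
    "PD(Amide-NH)",
    "PD(K+R+HIP)",
    "PD(K+N+Q)",
    "PD(W+H)",
    "PD(T+S+Y+D+E)",
    "PA(Amide-O)",
    "PA(D+E)",
    "PA(N+Q+T+S+D-H+E-H)",
    "PA(Y+H)",
    "PVol",
)

#: Default sphere extensions over the ligand maxD (Angstrom).
COM_EXTENSION = 0.9
HB_EXTENSION = 3.0

AROMATIC_RESIDUES = frozenset({"PHE", "TRP", "TYR", "HIS", "HID", "HIE", "HIP"})

# ---------------------------------------------------------------------------
# donor / acceptor mapping tables
# ---------------------------------------------------------------------------
# Keyed by (residue name, atom name).  Backbone amide atoms are handled
# separately: "N" of every residue except proline is an amide donor and "O"
# of every residue is an amide acceptor, irrespective of residue identity.
#
# Histidine tautomers: without hydrogens a neutral HIS is treated as the
# default NE2-H tautomer (NE2 donates, ND1 accepts); HID is the ND1-H
# tautomer; the doubly protonated HIP donates from both ring nitrogens and
# accepts with neither.  Protonated Asp/Glu (ASH/GLH) carry a hydroxyl that
# donates; their carbonyl oxygen remains a neutral acceptor.  Lysine NZ is
# assigned to the positively charged group only, never to the neutral amino
# group, so no atom is double counted.

DONOR_GROUP_MAP: dict[tuple[str, str], str] = {
    ("LYS", "NZ"): "PD(K+R+HIP)",
    ("ARG", "NE"): "PD(K+R+HIP)",
    ("ARG", "NH1"): "PD(K+R+HIP)",
    ("ARG", "NH2"): "PD(K+R+HIP)",
    ("HIP", "ND1"): "PD(K+R+HIP)",
    ("HIP", "NE2"): "PD(K+R+HIP)",
    ("ASN", "ND2"): "PD(K+N+Q)",
    ("GLN", "NE2"): "PD(K+N+Q)",
    ("TRP", "NE1"): "PD(W+H)",
    ("HIS", "NE2"): "PD(W+H)",
    ("HIE", "NE2"): "PD(W+H)",
    ("HID", "ND1"): "PD(W+H)",
    ("THR", "OG1"): "PD(T+S+Y+D+E)",
    ("SER", "OG"): "PD(T+S+Y+D+E)",
    ("TYR", "OH"): "PD(T+S+Y+D+E)",
    ("ASH", "OD2"): "PD(T+S+Y+D+E)",
    ("GLH", "OE2"): "PD(T+S+Y+D+E)",
}

ACCEPTOR_GROUP_MAP: dict[tuple[str, str], str] = {
    ("ASP", "OD1"): "PA(D+E)",
    ("ASP", "OD2"): "PA(D+E)",
    ("GLU", "OE1"): "PA(D+E)",
    ("GLU", "OE2"): "PA(D+E)",
    ("ASN", "OD1"): "PA(N+Q+T+S+D-H+E-H)",
    ("GLN", "OE1"): "PA(N+Q+T+S+D-H+E-H)",
    ("THR", "OG1"): "PA(N+Q+T+S+D-H+E-H)",
    ("SER", "OG"): "PA(N+Q+T+S+D-H+E-H)",
    ("ASH", "OD1"): "PA(N+Q+T+S+D-H+E-H)",
    ("ASH", "OD2"): "PA(N+Q+T+S+D-H+E-H)",
    ("GLH", "OE1"): "PA(N+Q+T+S+D-H+E-H)",
    ("GLH", "OE2"): "PA(N+Q+T+S+D-H+E-H)",
    ("TYR", "OH"): "PA(Y+H)",
    ("HIS", "ND1"): "PA(Y+H)",
    ("HIE", "ND1"): "PA(Y+H)",
    ("HID", "NE2"): "PA(Y+H)",
}

# ---------------------------------------------------------------------------
# per-residue Wildman-Crippen contribution totals
# ---------------------------------------------------------------------------
# Each standard residue is modelled as the central unit of an acetyl /
# N-methylamide capped dipeptide (neutral side-chain forms).  Per-atom
# Crippen contributions are summed over the residue's own atoms -- backbone
# N, CA, C, O plus side chain, with attached hydrogens attributed to their
# heavy atom -- excluding the two caps.  The totals therefore depend only on
# residue identity, not on which atoms were resolved in a crystal structure.

_CAPPED_SMILES = {
    "GLY": "CC(=O)NCC(=O)NC",
    "ALA": "CC(=O)NC(C)C(=O)NC",
    "VAL": "CC(=O)NC(C(C)C)C(=O)NC",
    "LEU": "CC(=O)NC(CC(C)C)C(=O)NC",
    "ILE": "CC(=O)NC(C(C)CC)C(=O)NC",
    "PRO": "CC(=O)N1CCCC1C(=O)NC",
    "PHE": "CC(=O)NC(Cc1ccccc1)C(=O)NC",
    "TRP": "CC(=O)NC(Cc1c[nH]c2ccccc12)C(=O)NC",
    "TYR": "CC(=O)NC(Cc1ccc(O)cc1)C(=O)NC",
    "HIS": "CC(=O)NC(Cc1c[nH]cn1)C(=O)NC",
    "SER": "CC(=O)NC(CO)C(=O)NC",
    "THR": "CC(=O)NC(C(C)O)C(=O)NC",
    "CYS": "CC(=O)NC(CS)C(=O)NC",
    "MET": "CC(=O)NC(CCSC)C(=O)NC",
    "ASN": "CC(=O)NC(CC(N)=O)C(=O)NC",
    "GLN": "CC(=O)NC(CCC(N)=O)C(=O)NC",
    "ASP": "CC(=O)NC(CC(O)=O)C(=O)NC",
    "GLU": "CC(=O)NC(CCC(O)=O)C(=O)NC",
    "LYS": "CC(=O)NC(CCCCN)C(=O)NC",
    "ARG": "CC(=O)NC(CCCNC(N)=N)C(=O)NC",
}

#: Protonation/bonding variants share the parent residue's Crippen totals.
_RESIDUE_ALIASES = {
    "HID": "HIS", "HIE": "HIS", "HIP": "HIS",
    "ASH": "ASP", "GLH": "GLU", "CYX": "CYS", "LYN": "LYS",
}


@lru_cache(maxsize=None)
def _residue_crippen(resname: str) -> tuple[float, float] | None:
    """(logP, MR) total for one residue unit, or None if unparameterized."""
    resname = _RESIDUE_ALIASES.get(resname, resname)
    smiles = _CAPPED_SMILES.get(resname)
    if smiles is None:
        return None
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    n_heavy = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)
    # SMILES parse order: atoms 0-2 are the acetyl cap, the last two heavy
    # atoms are the N-methylamide cap; everything between is the residue.
    central = set(range(3, n_heavy - 2))
    contribs = rdMolDescriptors._CalcCrippenContribs(mol)
    logp = mr = 0.0
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        if atom.GetAtomicNum() == 1:
            owner = atom.GetNeighbors()[0].GetIdx()
        else:
            owner = idx
        if owner in central:
            logp += contribs[idx][0]
            mr += contribs[idx][1]
    return logp, mr


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

@dataclass
class PocketSelection:
    """Residues and atoms inside the maxD-derived spheres."""

    center: np.ndarray
    maxD: float
    residues_com: list[Residue]
    atoms_hb: list[tuple[Residue, str, str, np.ndarray]]


def select_pocket(
    protein: ProteinStructure,
    center: np.ndarray,
    maxD: float,
    com_extension: float = COM_EXTENSION,
    hb_extension: float = HB_EXTENSION,
) -> PocketSelection:
    """Select pocket residues and atoms around ``center``.

    Residues enter ``residues_com`` when their center of mass lies within
    ``maxD + com_extension`` of the center; individual protein atoms enter
    ``atoms_hb`` within ``maxD + hb_extension``.  Both boundaries are
    inclusive.
    """
    if not (maxD > 0):
        raise ValueError(f"maxD must be positive, got {maxD}")
    center = np.asarray(center, dtype=float)
    r_com = maxD + com_extension
    r_hb = maxD + hb_extension

    residues_com = [
        res
        for res in protein.residues
        if np.linalg.norm(res.center_of_mass() - center) <= r_com
    ]
    atoms_hb = [
        (res, atom_name, element, xyz)
        for res, atom_name, element, xyz in protein.polymer_atoms()
        if np.linalg.norm(xyz - center) <= r_hb
    ]
    if not residues_com and not atoms_hb:
        warnings.warn("empty pocket selection: no residues or atoms in range",
                      stacklevel=2)
    return PocketSelection(center, maxD, residues_com, atoms_hb)


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def residue_group_descriptors(selection: PocketSelection) -> dict[str, float]:
    """The thirteen residue-derived pocket values, before maxD scaling."""
    values = {name: 0.0 for name in POCKET_FEATURE_NAMES if name != "PVol"}

    unknown: set[str] = set()
    for res in selection.residues_com:
        contrib = _residue_crippen(res.name)
        if contrib is None:
            unknown.add(res.name)
            continue
        logp, mr = contrib
        suffix = "(Arom)" if res.name in AROMATIC_RESIDUES else "(Non-Arom)"
        values["PlogP" + suffix] += logp
        values["PMR" + suffix] += mr

    for res, atom_name, element, _xyz in selection.atoms_hb:
        if element.upper() == "H":
            continue
        if atom_name == "N" and res.name != "PRO":
            values["PD(Amide-NH)"] += 1
        elif atom_name == "O":
            values["PA(Amide-O)"] += 1
        else:
            donor_group = DONOR_GROUP_MAP.get((res.name, atom_name))
            if donor_group is not None:
                values[donor_group] += 1
            acceptor_group = ACCEPTOR_GROUP_MAP.get((res.name, atom_name))
            if acceptor_group is not None:
                values[acceptor_group] += 1
            if (
                donor_group is None
                and acceptor_group is None
                and res.name not in _CAPPED_SMILES
                and res.name not in _RESIDUE_ALIASES
            ):
                unknown.add(res.name)

    if unknown:
        warnings.warn(
            f"unknown residue name(s) {sorted(unknown)}: counted in backbone "
            "features only", stacklevel=2,
        )
    return values


_VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
_VDW_DEFAULT = 1.70
PROBE_RADIUS = 1.4  # water-sized probe, Angstrom


def pocket_volume(
    protein: ProteinStructure,
    center: np.ndarray,
    maxD: float,
    grid: float = 0.5,
    probe: float = PROBE_RADIUS,
) -> float:
    """Solvent-accessible pocket volume (A^3) by grid-probe counting.

    Counts grid points inside the sphere of radius ``maxD`` around
    ``center`` that lie farther than (vdW radius + probe) from every protein
    heavy atom, times the grid cell volume.  Converges to the analytic open
    volume as the grid is refined.
    """
    if not (grid > 0):
        raise ValueError(f"grid spacing must be positive, got {grid}")
    if not (maxD > 0):
        raise ValueError(f"maxD must be positive, got {maxD}")
    center = np.asarray(center, dtype=float)

    ax = np.arange(-maxD, maxD + grid / 2, grid)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    pts = pts[np.linalg.norm(pts, axis=1) <= maxD] + center

    coords, radii = [], []
    for _, _, element, xyz in protein.polymer_atoms():
        el = element.upper()
        if el == "H":
            continue
        coords.append(xyz)
        radii.append(_VDW_RADII.get(el, _VDW_DEFAULT))
    if coords:
        coords = np.asarray(coords)
        radii = np.asarray(radii)
        # prune to atoms whose exclusion shell can reach the sphere
        reach = maxD + radii + probe
        keep = np.linalg.norm(coords - center[None, :], axis=1) <= reach
        coords, radii = coords[keep], radii[keep]
        open_mask = np.ones(len(pts), dtype=bool)
        for r in np.unique(radii):
            tree = cKDTree(coords[radii == r])
            dist, _ = tree.query(pts, k=1)
            open_mask &= dist > r + probe
        n_open = int(open_mask.sum())
    else:
        n_open = len(pts)
    return float(n_open * grid**3)


@dataclass(frozen=True)
class PocketDescriptors:
    """The fourteen pocket features, maxD-scaled where residue-derived."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(POCKET_FEATURE_NAMES):
            raise ValueError("pocket descriptor vector must have 14 entries")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(POCKET_FEATURE_NAMES, self.values))

    def __getitem__(self, name: str) -> float:
        return self.as_dict()[name]


def pocket_descriptors(
    protein: ProteinStructure,
    center: np.ndarray,
    maxD: float,
    grid: float = 0.5,
    probe: float = PROBE_RADIUS,
    com_extension: float = COM_EXTENSION,
    hb_extension: float = HB_EXTENSION,
) -> PocketDescriptors:
    """All fourteen pocket descriptors for a site of radius ``maxD``.

    The thirteen residue-derived values are divided by maxD; PVol is not
    residue-derived and stays unscaled.
    """
    selection = select_pocket(protein, center, maxD, com_extension, hb_extension)
    raw = residue_group_descriptors(selection)
    scaled = {name: value / maxD for name, value in raw.items()}
    scaled["PVol"] = pocket_volume(protein, center, maxD, grid=grid, probe=probe)
    return PocketDescriptors(tuple(scaled[name] for name in POCKET_FEATURE_NAMES))


def cofactor_in_pocket(
    protein: ProteinStructure,
    center: np.ndarray,
    maxD: float,
    com_extension: float = COM_EXTENSION,
    exclude: frozenset[str] = frozenset({"HOH", "WAT"}),
) -> bool:
    """Diagnostic: any non-water hetero heavy atom inside the residue sphere.

    Pockets holding cofactors are known failure modes for descriptor-based
    scoring; this flag lets screening results be stratified accordingly.
    """
    center = np.asarray(center, dtype=float)
    radius = maxD + com_extension
    for res in protein.hetero:
        if res.name in exclude:
            continue
        for _, element, xyz in res.atoms:
            if element.upper() == "H":
                continue
            if np.linalg.norm(xyz - center) <= radius:
                return True
    return False
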