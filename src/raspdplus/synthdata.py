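"""Synthetic fixtures: toy complexes and feature tables with planted signal.

Everything here is generated programmatically so the full pipeline can be
exercised without downloading any benchmark data.  Toy complexes are built
from a small library of hand-checkable ligands and idealized residue
templates placed at controlled distances from the pocket center; every
fixture ships with an expectations sidecar computed by brute-force oracle
code that is deliberately independent of the descriptor modules (networkx
breadth-first Wiener sums, hand-tabulated donor/acceptor maps, analytic
sphere volumes).  Synthetic feature tables draw twenty plausibly scaled
descriptor columns, couple the size-driven ones through a shared latent
factor (mimicking the strong MASS/MR/W correlations of real complexes), and
plant a known linear + interaction signal in the target dG.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from raspdplus.learners import FEATURE_COLUMNS, FeatureTable
from raspdplus.structio import (
    MolecularGraph,
    ProteinStructure,
    Residue,
    mol_from_smiles,
    write_ligand_sdf,
    write_protein_pdb,
)

__all__ = [
    "FIXTURE_SMILES",
    "fixture_ligand",
    "oracle_wiener",
    "oracle_max_distance",
    "oracle_sphere_volume",
    "ToyComplexSpec",
    "make_toy_complex",
    "SyntheticTableSpec",
    "GroundTruth",
    "make_feature_table",
    "make_screening_library",
]

# ---------------------------------------------------------------------------
# fixture ligand library (descriptor values are hand-checkable)
# ---------------------------------------------------------------------------

FIXTURE_SMILES: dict[str, str] = {
    "methane": "C",
    "ethanol": "CCO",
    "benzene": "c1ccccc1",
    "n-butane": "CCCC",
    "cyclohexane": "C1CCCCC1",
    "acetamide": "CC(N)=O",
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "isopentane": "CCC(C)C",
    "morpholine": "C1COCCN1",
    "imidazole": "c1c[nH]cn1",
}

#: Hand-derived donor/acceptor atom counts under the package rule set
#: (donors: N/O bearing H; acceptors: N/O minus nitro and pyrrole-type N-H).
FIXTURE_HBOND_EXPECTED: dict[str, tuple[int, int]] = {
    "methane": (0, 0),
    "ethanol": (1, 1),
    "benzene": (0, 0),
    "n-butane": (0, 0),
    "cyclohexane": (0, 0),
    "acetamide": (1, 2),
    "aspirin": (1, 4),
    "isopentane": (0, 0),
    "morpholine": (1, 2),
    "imidazole": (1, 1),  # N-H donates; only the pyridine-type N accepts
}


def fixture_ligand(name: str, embed3d: bool = True) -> MolecularGraph:
    """One fixture molecule, optionally with a deterministic 3D conformer."""
    if name not in FIXTURE_SMILES:
        raise KeyError(f"unknown fixture ligand {name!r}")
    return mol_from_smiles(FIXTURE_SMILES[name], name=name, embed3d=embed3d)


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the descriptor modules)
# ---------------------------------------------------------------------------

def oracle_wiener(mol: MolecularGraph) -> int:
    """Wiener index by breadth-first search over all heavy-atom pairs."""
    heavy = set(mol.heavy_indices())
    g = nx.Graph()
    g.add_nodes_from(heavy)
    g.add_edges_from((i, j) for i, j, _ in mol.bonds if i in heavy and j in heavy)
    total = 0
    for source, lengths in nx.all_pairs_shortest_path_length(g):
        total += sum(lengths.values())
    return total // 2


def oracle_max_distance(mol: MolecularGraph) -> float:
    """maxD recomputed directly: mass-weighted COM, then the farthest atom."""
    from raspdplus.structio import _atomic_mass

    coords = mol.coordinates
    masses = np.array([_atomic_mass(el) for el in mol.elements])
    com = np.average(coords, axis=0, weights=masses)
    return float(max(math.dist(tuple(p), tuple(com)) for p in coords))


def oracle_sphere_volume(radius: float) -> float:
    return 4.0 / 3.0 * math.pi * radius**3


#: Hand-tabulated donor/acceptor heavy atoms per residue type, used by the
#: toy-complex expectation oracle.  Backbone N (non-proline) and O are
#: implicit for every type.  Written out independently of the mapping table
#: in pocket_features so fixtures can catch mapping errors.
_ORACLE_SIDECHAIN_DONORS: dict[str, dict[str, str]] = {
    "SER": {"OG": "PD(T+S+Y+D+E)"},
    "ASP": {},
    "LYS": {"NZ": "PD(K+R+HIP)"},
    "PHE": {},
    "ALA": {},
    "GLY": {},
}
_ORACLE_SIDECHAIN_ACCEPTORS: dict[str, dict[str, str]] = {
    "SER": {"OG": "PA(N+Q+T+S+D-H+E-H)"},
    "ASP": {"OD1": "PA(D+E)", "OD2": "PA(D+E)"},
    "LYS": {},
    "PHE": {},
    "ALA": {},
    "GLY": {},
}

# Idealized residue templates: (atom name, element, xyz) with geometry close
# to standard bond lengths; used only to place residues at controlled
# center-of-mass distances, never as real structural models.
_RESIDUE_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": [
        ("N", "N", (-1.20, 0.80, 0.00)),
        ("CA", "C", (0.00, 0.00, 0.00)),
        ("C", "C", (1.30, 0.70, 0.00)),
        ("O", "O", (2.35, 0.05, 0.00)),
    ],
    "ALA": [
        ("N", "N", (-1.20, 0.80, 0.00)),
        ("CA", "C", (0.00, 0.00, 0.00)),
        ("C", "C", (1.30, 0.70, 0.00)),
        ("O", "O", (2.35, 0.05, 0.00)),
        ("CB", "C", (0.00, -1.00, 1.15)),
    ],
    "SER": [
        ("N", "N", (-1.20, 0.80, 0.00)),
        ("CA", "C", (0.00, 0.00, 0.00)),
        ("C", "C", (1.30, 0.70, 0.00)),
        ("O", "O", (2.35, 0.05, 0.00)),
        ("CB", "C", (0.00, -1.00, 1.15)),
        ("OG", "O", (0.10, -0.45, 2.45)),
    ],
    "ASP": [
        ("N", "N", (-1.20, 0.80, 0.00)),
        ("CA", "C", (0.00, 0.00, 0.00)),
        ("C", "C", (1.30, 0.70, 0.00)),
        ("O", "O", (2.35, 0.05, 0.00)),
        ("CB", "C", (0.00, -1.00, 1.15)),
        ("CG", "C", (0.10, -0.40, 2.50)),
        ("OD1", "O", (1.15, -0.55, 3.15)),
        ("OD2", "O", (-0.90, 0.30, 2.95)),
    ],
    "LYS": [
        ("N", "N", (-1.20, 0.80, 0.00)),
        ("CA", "C", (0.00, 0.00, 0.00)),
        ("C", "C", (1.30, 0.70, 0.00)),
        ("O", "O", (2.35, 0.05, 0.00)),
        ("CB", "C", (0.00, -1.00, 1.15)),
        ("CG", "C", (0.10, -0.45, 2.50)),
        ("CD", "C", (0.10, -1.45, 3.60)),
        ("CE", "C", (0.20, -0.90, 5.00)),
        ("NZ", "N", (0.20, -1.90, 6.00)),
    ],
    "PHE": [
        ("N", "N", (-1.20, 0.80, 0.00)),
        ("CA", "C", (0.00, 0.00, 0.00)),
        ("C", "C", (1.30, 0.70, 0.00)),
        ("O", "O", (2.35, 0.05, 0.00)),
        ("CB", "C", (0.00, -1.00, 1.15)),
        ("CG", "C", (0.10, -0.45, 2.50)),
        ("CD1", "C", (1.30, -0.25, 3.20)),
        ("CD2", "C", (-1.10, -0.15, 3.20)),
        ("CE1", "C", (1.30, 0.25, 4.50)),
        ("CE2", "C", (-1.10, 0.35, 4.50)),
        ("CZ", "C", (0.10, 0.50, 5.20)),
    ],
}


@dataclass
class ToyComplexSpec:
    """Recipe for a toy complex.

    ``residues`` lists ``(residue type, com_offset)`` pairs: each residue's
    center of mass is placed at distance ``maxD + com_offset`` from the
    pocket center (the ligand center of mass), in a direction drawn from the
    seeded generator.
    """

    ligand: str = "benzene"
    residues: list[tuple[str, float]] = field(default_factory=list)
    seed: int = 0
    min_separation: float = 2.5  # Angstrom between residue COMs


def make_toy_complex(
    spec: ToyComplexSpec, out_dir: str | Path | None = None
) -> tuple[ProteinStructure, MolecularGraph, dict]:
    """Build a toy complex and its oracle-computed expectations sidecar.

    Returns ``(protein, ligand, expected)`` where ``expected`` holds the
    ligand Wiener index and hydrogen-bond counts, maxD, the per-group pocket
    donor/acceptor counts implied by the recipe (counted atom-by-atom
    against the hand-tabulated oracle maps), and the analytic empty-sphere
    volume when the recipe places no residue inside the volume sphere.
    With ``out_dir`` the complex is also written as PDB + SDF + JSON.
    """
    ligand = fixture_ligand(spec.ligand, embed3d=True)
    maxd = oracle_max_distance(ligand)
    coords = ligand.coordinates
    from raspdplus.structio import _atomic_mass

    masses = np.array([_atomic_mass(el) for el in ligand.elements])
    center = np.average(coords, axis=0, weights=masses)

    rng = np.random.default_rng(spec.seed)
    residues: list[Residue] = []
    placed_coms: list[np.ndarray] = []
    for idx, (restype, offset) in enumerate(spec.residues):
        if restype not in _RESIDUE_TEMPLATES:
            raise KeyError(f"no template for residue type {restype!r}")
        template = _RESIDUE_TEMPLATES[restype]
        t_coords = np.array([xyz for _, _, xyz in template])
        t_masses = np.array([_atomic_mass(el) for _, el, _ in template])
        t_com = np.average(t_coords, axis=0, weights=t_masses)

        target = None
        for _attempt in range(200):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            cand = center + direction * (maxd + offset)
            if all(
                np.linalg.norm(cand - prev) >= spec.min_separation
                for prev in placed_coms
            ):
                target = cand
                break
        if target is None:
            raise ValueError("infeasible geometry: cannot place residues "
                             "without clashes")
        placed_coms.append(target)
        shifted = t_coords - t_com + target
        residues.append(
            Residue(
                restype,
                "A",
                idx + 1,
                [
                    (name, el, shifted[a])
                    for a, (name, el, _) in enumerate(template)
                ],
            )
        )

    protein = ProteinStructure(residues or [_far_dummy(center, maxd)], name="toy")

    # -- oracle expectations ------------------------------------------------
    groups = {
        "PD(Amide-NH)": 0, "PD(K+R+HIP)": 0, "PD(K+N+Q)": 0, "PD(W+H)": 0,
        "PD(T+S+Y+D+E)": 0, "PA(Amide-O)": 0, "PA(D+E)": 0,
        "PA(N+Q+T+S+D-H+E-H)": 0, "PA(Y+H)": 0,
    }
    r_hb = maxd + 3.0
    for res in protein.residues:
        if res.name == "DUM":
            continue
        donors = _ORACLE_SIDECHAIN_DONORS.get(res.name, {})
        acceptors = _ORACLE_SIDECHAIN_ACCEPTORS.get(res.name, {})
        for atom_name, _el, xyz in res.atoms:
            if math.dist(tuple(xyz), tuple(center)) > r_hb:
                continue
            if atom_name == "N":
                groups["PD(Amide-NH)"] += 1
            elif atom_name == "O":
                groups["PA(Amide-O)"] += 1
            else:
                if atom_name in donors:
                    groups[donors[atom_name]] += 1
                if atom_name in acceptors:
                    groups[acceptors[atom_name]] += 1

    min_atom_dist = min(
        (
            math.dist(tuple(xyz), tuple(center))
            for res in protein.residues
            for _n, _e, xyz in res.atoms
            if res.name != "DUM"
        ),
        default=float("inf"),
    )
    expected = {
        "ligand": spec.ligand,
        "center": [float(v) for v in center],
        "W": oracle_wiener(ligand),
        "hbond": FIXTURE_HBOND_EXPECTED[spec.ligand],
        "maxD": maxd,
        "pocket_counts_raw": groups,
        "pocket_counts_scaled": {k: v / maxd for k, v in groups.items()},
        # empty-sphere analytic volume applies when no pocket atom can carve
        # out grid points (atom + probe shells stay outside the sphere)
        "empty_sphere_volume": (
            oracle_sphere_volume(maxd) if min_atom_dist > maxd + 3.2 else None
        ),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_protein_pdb(protein, out_dir / "protein.pdb")
        write_ligand_sdf([ligand], out_dir / "ligand.sdf")
        with open(out_dir / "expected.json", "w") as fh:
            json.dump(
                {k: (v if not isinstance(v, tuple) else list(v))
                 for k, v in expected.items()},
                fh, indent=2, sort_keys=True,
            )
    return protein, ligand, expected


def _far_dummy(center: np.ndarray, maxd: float) -> Residue:
    """A placeholder residue far outside every sphere (empty-pocket recipes)."""
    pos = np.asarray(center, dtype=float) + np.array([maxd + 50.0, 0.0, 0.0])
    return Residue("DUM", "Z", 999, [("C", "C", pos)])


# ---------------------------------------------------------------------------
# synthetic feature tables
# ---------------------------------------------------------------------------

#: Default planted coefficients (kcal/mol per raw feature unit); signs follow
#: the physical intuition that bigger, greasier ligands in richer pockets
#: bind more tightly (more negative dG).
DEFAULT_BETA: dict[str, float] = {
    "MASS": -0.004, "D": -0.08, "A": -0.06, "logP": -0.15, "MR": -0.025,
    "W": -0.0004,
    "PMR(Arom)": -0.008, "PMR(Non-Arom)": -0.006,
    "PlogP(Arom)": -0.15, "PlogP(Non-Arom)": -0.12,
    "PD(Amide-NH)": -0.25, "PD(K+R+HIP)": -0.20, "PD(K+N+Q)": -0.20,
    "PD(W+H)": -0.15, "PD(T+S+Y+D+E)": -0.20,
    "PA(Amide-O)": -0.30, "PA(D+E)": -0.25, "PA(N+Q+T+S+D-H+E-H)": -0.20,
    "PA(Y+H)": -0.15,
    "PVol": -0.0008,
}
DEFAULT_INTERCEPT = -2.0


@dataclass
class SyntheticTableSpec:
    """Generator settings for a planted-signal feature table."""

    n: int = 600
    beta: dict[str, float] | None = None  # None -> DEFAULT_BETA
    intercept: float = DEFAULT_INTERCEPT
    # (feature_i, feature_j, coefficient); applied to z-scored columns so the
    # coefficient is in kcal/mol per (sd x sd)
    interactions: list[tuple[str, str, float]] = field(default_factory=list)
    noise_sd: float = 1.0  # kcal/mol
    size_coupling: float = 0.6  # shared latent driving MASS/MR/W/PVol
    seed: int = 0


@dataclass
class GroundTruth:
    beta: dict[str, float]
    intercept: float
    interactions: list[tuple[str, str, float]]
    noise_sd: float


def make_feature_table(spec: SyntheticTableSpec) -> tuple[FeatureTable, GroundTruth]:
    """Draw a synthetic 20-feature table with a known signal in dG."""
    if spec.n < 48:
        raise ValueError(f"need n >= 48 rows, got {spec.n}")
    beta = dict(DEFAULT_BETA) if spec.beta is None else dict(spec.beta)
    unknown = set(beta) - set(FEATURE_COLUMNS)
    if unknown or len(beta) != len(FEATURE_COLUMNS):
        raise ValueError(
            "beta must assign exactly the 20 canonical features; "
            f"unknown={sorted(unknown)}"
        )
    for fi, fj, _c in spec.interactions:
        if fi not in FEATURE_COLUMNS or fj not in FEATURE_COLUMNS:
            raise ValueError(f"unknown interaction features ({fi}, {fj})")

    rng = np.random.default_rng(spec.seed)
    n = spec.n
    size = rng.normal(size=n)  # latent molecular-size factor
    c = spec.size_coupling

    def mix(base: np.ndarray, coupled: bool) -> np.ndarray:
        return base + c * size * np.std(base) if coupled else base

    cols: dict[str, np.ndarray] = {}
    cols["MASS"] = np.clip(mix(rng.normal(350, 70, n), True), 80, None)
    cols["D"] = rng.poisson(2.0, n).astype(float)
    cols["A"] = rng.poisson(4.0, n).astype(float)
    cols["logP"] = rng.normal(2.0, 1.5, n)
    cols["MR"] = np.clip(mix(rng.normal(90, 18, n), True), 20, None)
    cols["W"] = np.round(np.clip(mix(rng.normal(1200, 380, n), True), 40, None))
    cols["PMR(Arom)"] = rng.gamma(2.0, 14.0, n)
    cols["PMR(Non-Arom)"] = np.clip(mix(rng.gamma(5.0, 14.0, n), True), 1, None)
    cols["PlogP(Arom)"] = rng.gamma(2.0, 0.35, n)
    cols["PlogP(Non-Arom)"] = rng.normal(0.6, 0.9, n)
    cols["PD(Amide-NH)"] = rng.gamma(3.0, 0.6, n)
    cols["PD(K+R+HIP)"] = rng.gamma(1.5, 0.4, n)
    cols["PD(K+N+Q)"] = rng.gamma(1.5, 0.4, n)
    cols["PD(W+H)"] = rng.gamma(1.2, 0.3, n)
    cols["PD(T+S+Y+D+E)"] = rng.gamma(2.0, 0.5, n)
    cols["PA(Amide-O)"] = rng.gamma(3.0, 0.6, n)
    cols["PA(D+E)"] = rng.gamma(1.5, 0.5, n)
    cols["PA(N+Q+T+S+D-H+E-H)"] = rng.gamma(2.0, 0.5, n)
    cols["PA(Y+H)"] = rng.gamma(1.2, 0.3, n)
    cols["PVol"] = np.clip(mix(rng.uniform(200, 1400, n), True), 50, None)

    X = pd.DataFrame({name: cols[name] for name in FEATURE_COLUMNS})
    y = np.full(n, spec.intercept, dtype=float)
    for name in FEATURE_COLUMNS:
        y += beta[name] * X[name].to_numpy()
    for fi, fj, coef in spec.interactions:
        zi = (X[fi] - X[fi].mean()) / X[fi].std(ddof=0)
        zj = (X[fj] - X[fj].mean()) / X[fj].std(ddof=0)
        y += coef * (zi * zj).to_numpy()
    if spec.noise_sd > 0:
        y += rng.normal(0.0, spec.noise_sd, n)

    ids = [f"synth{i:05d}" for i in range(n)]
    table = FeatureTable(ids, X, y)
    return table, GroundTruth(beta, spec.intercept, list(spec.interactions),
                              spec.noise_sd)


# ---------------------------------------------------------------------------
# synthetic screening library
# ---------------------------------------------------------------------------

def make_screening_library(
    n_active: int = 10,
    n_decoy: int = 50,
    seed: int = 0,
) -> tuple[list[MolecularGraph], set[str]]:
    """Actives and decoys distinguished by molecular size (hence MR).

    Actives are long branched alkanes/alcohols (high molar refractivity),
    decoys short ones; a model trained on MR-driven dG should rank the
    actives ahead of the decoys.
    """
    rng = np.random.default_rng(seed)
    mols: list[MolecularGraph] = []
    actives: set[str] = set()
    for i in range(n_active):
        length = int(rng.integers(14, 20))
        smiles = "C" * length + ("O" if rng.random() < 0.5 else "")
        name = f"active{i:03d}"
        mols.append(mol_from_smiles(smiles, name=name, embed3d=True))
        actives.add(name)
    for i in range(n_decoy):
        length = int(rng.integers(3, 8))
        smiles = "C" * length + ("O" if rng.random() < 0.5 else "")
        mols.append(mol_from_smiles(smiles, name=f"decoy{i:03d}", embed3d=True))
    return mols, actives
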