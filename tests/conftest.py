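"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from raspdplus.structio import MolecularGraph
from raspdplus.synthdata import (
    SyntheticTableSpec,
    ToyComplexSpec,
    make_feature_table,
    make_toy_complex,
)


def chain_graph(n: int, element: str = "C") -> MolecularGraph:
    """A path graph of n heavy atoms (no coordinates)."""
    return MolecularGraph(
        atoms=[(element, None, 0, False) for _ in range(n)],
        bonds=[(i, i + 1, 1.0) for i in range(n - 1)],
        name=f"chain{n}",
    )


def random_connected_graph(rng: np.random.Generator, max_nodes: int = 15
                           ) -> MolecularGraph:
    """Random connected heavy-atom graph: random tree plus extra edges."""
    n = int(rng.integers(2, max_nodes + 1))
    bonds = {(int(rng.integers(0, i)), i) for i in range(1, n)}
    for _ in range(int(rng.integers(0, n))):
        i, j = sorted(rng.choice(n, size=2, replace=False).tolist())
        bonds.add((int(i), int(j)))
    return MolecularGraph(
        atoms=[("C", None, 0, False) for _ in range(n)],
        bonds=[(i, j, 1.0) for i, j in sorted(bonds)],
        name="random",
    )


@pytest.fixture(scope="session")
def synth600():
    """The 600-row planted-signal table used by protocol-level tests."""
    return make_feature_table(SyntheticTableSpec(n=600, seed=11))


@pytest.fixture(scope="session")
def glycine_complex():
    """Benzene ligand with a single glycine at COM distance maxD + 0.5."""
    return make_toy_complex(
        ToyComplexSpec(ligand="benzene", residues=[("GLY", 0.5)], seed=3)
    )


@pytest.fixture(scope="session")
def aspartate_complex():
    """Benzene ligand with a single aspartate at COM distance maxD + 0.4."""
    return make_toy_complex(
        ToyComplexSpec(ligand="benzene", residues=[("ASP", 0.4)], seed=5)
    )


@pytest.fixture(scope="session")
def mixed_pocket_complex():
    """Five-residue pocket covering every donor/acceptor group in the maps."""
    return make_toy_complex(
        ToyComplexSpec(
            ligand="aspirin",
            residues=[("GLY", 0.5), ("ASP", 0.3), ("SER", 0.6),
                      ("LYS", 0.2), ("PHE", 0.4)],
            seed=7,
        )
    )
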