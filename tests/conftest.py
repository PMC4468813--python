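"""Shared fixtures: small synthetic structures built in memory."""

import numpy as np
import pytest

from dockbox.chem_io import (
    LigandStructure,
    ProteinResidue,
    ProteinStructure,
)
from dockbox.geometry import PocketSpec


@pytest.fixture
def two_atom_ligand() -> LigandStructure:
    """Two heavy atoms 2 A apart: Rg is exactly 1.0 A."""
    return LigandStructure(
        "two-atom", ["C", "C"], np.array([[[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]])
    )


@pytest.fixture
def ethanol_like_ligand() -> LigandStructure:
    """Three heavy atoms plus hydrogens, ethanol-style composition."""
    elements = ["C", "C", "O", "H", "H", "H", "H", "H", "H"]
    rng = np.random.default_rng(11)
    coords = rng.normal(scale=1.2, size=(9, 3))
    return LigandStructure("ethanol-like", elements, coords[None])


@pytest.fixture
def random_ligand_factory():
    """Build random all-carbon ligands of a requested size."""

    def make(n_atoms: int, seed: int = 0, n_conformers: int = 1) -> LigandStructure:
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-8, 8, size=(n_conformers, n_atoms, 3))
        return LigandStructure(f"random-{n_atoms}-{seed}", ["C"] * n_atoms, coords)

    return make


@pytest.fixture
def shell_protein() -> ProteinStructure:
    """Eight single-atom residues at the corners of a 6 A cube."""
    corners = np.array(
        [[x, y, z] for x in (-3.0, 3.0) for y in (-3.0, 3.0) for z in (-3.0, 3.0)]
    )
    residues = [
        ProteinResidue("A", i + 1, "PSD", ["C"], corner[None, :])
        for i, corner in enumerate(corners)
    ]
    return ProteinStructure("shell", residues)


@pytest.fixture
def origin_pocket() -> PocketSpec:
    return PocketSpec((0.0, 0.0, 0.0))


def make_protein_chain(n_residues: int, atoms_per_residue: int = 3) -> ProteinStructure:
    """A stick polymer: residues spaced 3 A apart along x."""
    rng = np.random.default_rng(5)
    residues = []
    for i in range(n_residues):
        coords = np.array([3.0 * i, 0.0, 0.0]) + rng.normal(
            scale=0.5, size=(atoms_per_residue, 3)
        )
        residues.append(
            ProteinResidue("A", i + 1, "ALA", ["C"] * atoms_per_residue, coords)
        )
    return ProteinStructure(f"chain-{n_residues}", residues)


@pytest.fixture
def protein_chain_factory():
    return make_protein_chain
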