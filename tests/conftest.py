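"""Shared fixtures: hand-built and embedded small molecules, synthetic sets."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from molaudit.molecule import Molecule, from_rdkit
from molaudit.synthetic import GeneratorConfig, generate_molecule_set


def mol_from_smiles_3d(smi: str, mol_id: str, seed: int = 7, label: str = "train") -> Molecule:
    rd = Chem.AddHs(Chem.MolFromSmiles(smi))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    assert AllChem.EmbedMolecule(rd, params) == 0
    AllChem.MMFFOptimizeMolecule(rd, maxIters=500)
    return from_rdkit(rd, mol_id, label)


@pytest.fixture(scope="session")
def methane() -> Molecule:
    d = 1.089 / np.sqrt(3.0)
    coords = np.array(
        [[0, 0, 0], [d, d, d], [-d, -d, d], [-d, d, -d], [d, -d, -d]], dtype=float
    )
    return Molecule(
        "methane", ["C", "H", "H", "H", "H"], coords=coords,
        bonds=[(0, k, 1, False) for k in range(1, 5)], orders_assigned=True,
    )


@pytest.fixture(scope="session")
def ethyne() -> Molecule:
    coords = np.array([[0, 0, 0], [1.203, 0, 0], [-1.06, 0, 0], [2.263, 0, 0]])
    return Molecule("ethyne", ["C", "C", "H", "H"], coords=coords)


@pytest.fixture(scope="session")
def ethene() -> Molecule:
    coords = np.array(
        [[0, 0, 0], [1.339, 0, 0],
         [-0.56, 0.92, 0], [-0.56, -0.92, 0], [1.899, 0.92, 0], [1.899, -0.92, 0]]
    )
    return Molecule("ethene", ["C", "C", "H", "H", "H", "H"], coords=coords)


@pytest.fixture(scope="session")
def benzene() -> Molecule:
    r_c, r_h = 1.397, 2.481
    coords = []
    for k in range(6):
        a = np.pi / 3.0 * k
        coords.append([r_c * np.cos(a), r_c * np.sin(a), 0.0])
    for k in range(6):
        a = np.pi / 3.0 * k
        coords.append([r_h * np.cos(a), r_h * np.sin(a), 0.0])
    return Molecule("benzene", ["C"] * 6 + ["H"] * 6, coords=np.array(coords))


@pytest.fixture(scope="session")
def water() -> Molecule:
    coords = np.array([[0, 0, 0], [0.9572, 0, 0], [-0.2399, 0.9266, 0]])
    return Molecule(
        "water", ["O", "H", "H"], coords=coords,
        bonds=[(0, 1, 1, False), (0, 2, 1, False)], orders_assigned=True,
    )


@pytest.fixture(scope="session")
def ethanol() -> Molecule:
    return mol_from_smiles_3d("CCO", "ethanol")


@pytest.fixture(scope="session")
def ethane() -> Molecule:
    return mol_from_smiles_3d("CC", "ethane")


@pytest.fixture(scope="session")
def cyclohexane() -> Molecule:
    return mol_from_smiles_3d("C1CCCCC1", "cyclohexane")


@pytest.fixture(scope="session")
def cyclohexene() -> Molecule:
    return mol_from_smiles_3d("C1=CCCCC1", "cyclohexene")


@pytest.fixture(scope="session")
def base_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def small_set(base_config) -> list[Molecule]:
    """100 canonicalized synthetic molecules (graphs only)."""
    return generate_molecule_set(base_config, 100, seed=11, label="train")


@pytest.fixture(scope="session")
def medium_set(base_config) -> list[Molecule]:
    """500 canonicalized synthetic molecules (graphs only)."""
    return generate_molecule_set(base_config, 500, seed=23, label="train")
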