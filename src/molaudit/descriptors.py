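"""Per-molecule vectorizations used by the latent map and the discriminator.

Three descriptor families:

* the averaged SOAP-style *structural* descriptor (:mod:`molaudit.soap`),
  encoding 3D geometry;
* the engineered *bonding* descriptor — element counts, bond-type x
  element-pair counts, ring size x class counts, functional-group match
  counts, and a few global scalars (molecular weight, heavy-atom count,
  hydrogen fraction, rotatable bonds). The schema is an explicit, versioned
  feature list and is the source of truth for feature order;
* hashed Morgan (circular) *fingerprints* for the train-vs-generated
  discriminator, optionally augmented with heavy-atom and per-element counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit.Chem.rdMolDescriptors import CalcNumRotatableBonds

from .molecule import Molecule, ensure_rdkit
from .soap import StructuralDescriptorConfig, structural_descriptor  # noqa: F401
from .substructure import (
    RING_CLASSES,
    GroupCatalog,
    _classify_ring,
    group_match_counts,
)

BOND_TYPES = ("single", "double", "triple", "aromatic")
RING_SIZES = (3, 4, 5, 6, 7, 8)
GLOBAL_SCALARS = ("molecular_weight", "heavy_atom_count", "h_fraction", "rotatable_bonds")


@dataclass
class DescriptorMatrix:
    """Per-molecule numeric vectors with a feature-name registry."""

    X: np.ndarray
    feature_names: list[str]
    ids: list[str] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.feature_names):
            raise ValueError("X must be (n_molecules, n_features) matching the registry")

    def __len__(self) -> int:
        return self.X.shape[0]

    @staticmethod
    def concat(mats: Sequence["DescriptorMatrix"]) -> "DescriptorMatrix":
        names = mats[0].feature_names
        for m in mats[1:]:
            if m.feature_names != names:
                raise ValueError("feature registries differ; cannot concatenate")
        return DescriptorMatrix(
            X=np.vstack([m.X for m in mats]),
            feature_names=list(names),
            ids=[i for m in mats for i in m.ids],
            labels=[l for m in mats for l in m.labels],
        )


@dataclass
class BondingDescriptorSchema:
    """Ordered feature list for the bonding descriptor.

    schema_version identifies the default layout; custom schemas can restrict
    ``feature_names`` to any subset of the default feature universe. The
    default species alphabet covers the 16 elements of diverse organic
    crystal databases, giving a ~620-feature schema.
    """

    species: tuple[str, ...] = (
        "H", "Li", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "As",
        "Se", "Br", "Te", "I",
    )
    catalog: Optional[GroupCatalog] = None
    feature_names: list[str] = field(default_factory=list)
    schema_version: str = "1"

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        if self.catalog is None:
            self.catalog = GroupCatalog.default()
        if not self.feature_names:
            self.feature_names = self._default_features()
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    def _default_features(self) -> list[str]:
        names = [f"n_{el}" for el in self.species]
        pairs = [
            (self.species[a], self.species[b])
            for a in range(len(self.species))
            for b in range(a, len(self.species))
        ]
        for ea, eb in pairs:
            for bt in BOND_TYPES:
                names.append(f"bond_{bt}[{ea},{eb}]")
        for size in RING_SIZES:
            for cls in RING_CLASSES:
                names.append(f"ring_{cls}_size{size}")
        names.extend(f"group_{g}" for g in self.catalog.names())
        names.extend(GLOBAL_SCALARS)
        return names

    def __len__(self) -> int:
        return len(self.feature_names)


def _bond_type(order: int, aromatic: bool) -> str:
    if aromatic:
        return "aromatic"
    return {1: "single", 2: "double", 3: "triple"}[order]


def bonding_descriptor(mol: Molecule, schema: Optional[BondingDescriptorSchema] = None) -> np.ndarray:
    """Deterministic feature extraction in schema order."""
    schema = schema or BondingDescriptorSchema()
    if not mol.orders_assigned:
        raise ValueError(f"{mol.id}: bond orders must be assigned first")
    rd = ensure_rdkit(mol)

    values: dict[str, float] = {f"n_{el}": 0.0 for el in schema.species}
    for e in mol.elements:
        key = f"n_{e}"
        if key in values:
            values[key] += 1.0

    rank = {el: k for k, el in enumerate(schema.species)}
    for i, j, order, arom in mol.bonds:
        ea, eb = sorted(
            (mol.elements[i], mol.elements[j]),
            key=lambda e: rank.get(e, len(rank)),
        )
        key = f"bond_{_bond_type(order, arom)}[{ea},{eb}]"
        values[key] = values.get(key, 0.0) + 1.0

    rd_rings = [tuple(r) for r in Chem.GetSymmSSSR(rd)]
    for ring in rd_rings:
        size = min(max(len(ring), RING_SIZES[0]), RING_SIZES[-1])
        key = f"ring_{_classify_ring(rd, ring)}_size{size}"
        values[key] = values.get(key, 0.0) + 1.0

    for g, cnt in group_match_counts(mol, schema.catalog).items():
        values[f"group_{g}"] = float(cnt)

    values["molecular_weight"] = mol.molecular_weight
    values["heavy_atom_count"] = float(mol.n_heavy)
    values["h_fraction"] = mol.n_hydrogens / mol.n_atoms
    values["rotatable_bonds"] = float(CalcNumRotatableBonds(rd))

    return np.array([values.get(name, 0.0) for name in schema.feature_names])


@dataclass
class FingerprintConfig:
    radius: int = 2
    n_bits: int = 2048
    augment_counts: bool = True

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.n_bits < 1 or (self.n_bits & (self.n_bits - 1)) != 0:
            raise ValueError("n_bits must be a power of two")


def circular_fingerprint(
    mol: Molecule,
    cfg: Optional[FingerprintConfig] = None,
    species: tuple[str, ...] = ("H", "C", "N", "O", "F", "S", "Cl"),
) -> np.ndarray:
    """Hashed Morgan bits; with ``augment_counts`` the heavy-atom total and
    per-element counts are appended as integer features."""
    cfg = cfg or FingerprintConfig()
    rd = ensure_rdkit(mol)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=cfg.radius, fpSize=cfg.n_bits)
    bits = np.array(gen.GetFingerprintAsNumPy(rd), dtype=float)
    if not cfg.augment_counts:
        return bits
    counts = [float(mol.n_heavy)] + [
        float(sum(1 for e in mol.elements if e == sp)) for sp in species
    ]
    return np.concatenate([bits, counts])


def fingerprint_feature_names(
    cfg: FingerprintConfig,
    species: tuple[str, ...] = ("H", "C", "N", "O", "F", "S", "Cl"),
) -> list[str]:
    names = [f"fp_bit_{k}" for k in range(cfg.n_bits)]
    if cfg.augment_counts:
        names.append("heavy_atom_count")
        names.extend(f"n_{sp}" for sp in species)
    return names


def featurize_set(
    mols: Sequence[Molecule],
    kind: str = "fingerprint",
    fp_cfg: Optional[FingerprintConfig] = None,
    schema: Optional[BondingDescriptorSchema] = None,
    structural_cfg: Optional[StructuralDescriptorConfig] = None,
    species: tuple[str, ...] = ("H", "C", "N", "O", "F", "S", "Cl"),
) -> DescriptorMatrix:
    """Vectorize a whole molecule set into a :class:`DescriptorMatrix`."""
    if kind == "fingerprint":
        cfg = fp_cfg or FingerprintConfig()
        X = np.stack([circular_fingerprint(m, cfg, species) for m in mols])
        names = fingerprint_feature_names(cfg, species)
    elif kind == "bonding":
        schema = schema or BondingDescriptorSchema(species=species)
        X = np.stack([bonding_descriptor(m, schema) for m in mols])
        names = list(schema.feature_names)
    elif kind == "structural":
        cfg2 = structural_cfg or StructuralDescriptorConfig(species=species)
        X = np.stack([structural_descriptor(m, cfg2) for m in mols])
        names = cfg2.feature_names()
    else:
        raise ValueError(f"unknown descriptor kind {kind!r}")
    return DescriptorMatrix(
        X=X,
        feature_names=names,
        ids=[m.id for m in mols],
        labels=[m.label for m in mols],
    )
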