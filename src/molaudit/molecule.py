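"""The in-memory molecule container and its RDKit bridge.

A :class:`Molecule` is a plain record: element symbols, optional 3D
coordinates (Å), an optional bond table, and bookkeeping for the audit
(dataset label, perception validity, canonical SMILES). Heavier chemistry
(aromaticity, ring perception, fingerprints) is delegated to RDKit through
:func:`to_rdkit` / :func:`from_rdkit`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem  # noqa: F401  (registers coordinate code)
from rdkit import RDLogger

from .periodic import atomic_mass

RDLogger.DisableLog("rdApp.*")

#: bond table entry: (atom_i, atom_j, order in {1,2,3}, aromatic flag);
#: i < j and each pair stored once.
Bond = tuple[int, int, int, bool]

_ORDER_TO_RDKIT = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}


@dataclass
class Molecule:
    """One molecule of a train or generated set."""

    id: str
    elements: list[str]
    coords: Optional[np.ndarray] = None
    bonds: list[Bond] = field(default_factory=list)
    smiles: Optional[str] = None
    label: str = "train"
    #: True once bond orders/aromaticity have been assigned (SDF input,
    #: the synthetic generator, or assign_bond_orders_and_aromaticity).
    orders_assigned: bool = False
    valid: bool = True
    invalid_reason: Optional[str] = None
    _rdmol: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
            if len(self.coords) != len(self.elements):
                raise ValueError(
                    f"{self.id}: {len(self.elements)} elements but "
                    f"{len(self.coords)} coordinates"
                )
        n = len(self.elements)
        seen: set[tuple[int, int]] = set()
        norm: list[Bond] = []
        for i, j, order, arom in self.bonds:
            if i == j:
                raise ValueError(f"{self.id}: self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"{self.id}: bond ({i},{j}) outside {n} atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"{self.id}: bond {key} stored twice")
            seen.add(key)
            norm.append((key[0], key[1], int(order), bool(arom)))
        self.bonds = norm

    # -- simple derived quantities -------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_heavy(self) -> int:
        return sum(1 for e in self.elements if e != "H")

    @property
    def n_hydrogens(self) -> int:
        return sum(1 for e in self.elements if e == "H")

    @property
    def molecular_weight(self) -> float:
        # fsum: exactly rounded, hence invariant to atom ordering
        import math

        return math.fsum(atomic_mass(e) for e in self.elements)

    def with_(self, **changes) -> "Molecule":
        return replace(self, **changes)


def to_rdkit(mol: Molecule, sanitize: bool = True) -> Chem.Mol:
    """Build an RDKit molecule mirroring ``mol``'s atoms, bonds and coords.

    Bond orders in the table are Kekulé orders; sanitization re-perceives
    aromaticity. All hydrogens in the table stay explicit.
    """
    rw = Chem.RWMol()
    for el in mol.elements:
        atom = Chem.Atom(el)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for i, j, order, _arom in mol.bonds:
        rw.AddBond(i, j, _ORDER_TO_RDKIT.get(order, Chem.BondType.SINGLE))
    out = rw.GetMol()
    if mol.coords is not None:
        conf = Chem.Conformer(mol.n_atoms)
        for k, (x, y, z) in enumerate(mol.coords):
            conf.SetAtomPosition(k, (float(x), float(y), float(z)))
        out.AddConformer(conf, assignId=True)
    if sanitize:
        Chem.SanitizeMol(out)
    return out


def from_rdkit(rdmol: Chem.Mol, mol_id: str, label: str = "train") -> Molecule:
    """Convert an RDKit molecule (hydrogens explicit) to a :class:`Molecule`."""
    elements = [a.GetSymbol() for a in rdmol.GetAtoms()]
    coords = None
    if rdmol.GetNumConformers() > 0:
        coords = np.array(rdmol.GetConformer().GetPositions(), dtype=float)
    kek = Chem.Mol(rdmol)
    Chem.Kekulize(kek, clearAromaticFlags=False)
    bonds: list[Bond] = []
    for b, bk in zip(rdmol.GetBonds(), kek.GetBonds()):
        order = int(round(bk.GetBondTypeAsDouble()))
        bonds.append(
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), max(order, 1), b.GetIsAromatic())
        )
    smiles = Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(rdmol)))
    return Molecule(
        id=mol_id,
        elements=elements,
        coords=coords,
        bonds=bonds,
        smiles=smiles,
        label=label,
        orders_assigned=True,
        _rdmol=rdmol,
    )


def ensure_rdkit(mol: Molecule) -> Chem.Mol:
    """Return a sanitized RDKit mol for ``mol``, caching it on the record.

    Raises ``ValueError`` for molecules flagged invalid by perception.
    """
    if not mol.valid:
        raise ValueError(f"{mol.id}: perception-invalid ({mol.invalid_reason})")
    if mol._rdmol is None:
        mol._rdmol = to_rdkit(mol, sanitize=True)
    return mol._rdmol


def connected_components(mol: Molecule) -> int:
    """Number of connected components of the bond graph (isolated atoms count)."""
    n = mol.n_atoms
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j, _o, _a in mol.bonds:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    return len({find(k) for k in range(n)})


def pairwise_distance(mol: Molecule, i: int, j: int) -> float:
    return float(np.linalg.norm(mol.coords[i] - mol.coords[j]))


def molecules_to_frame(mols: Sequence[Molecule]):
    """Set-level summary table (one row per molecule) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [m.id for m in mols],
            "label": [m.label for m in mols],
            "n_atoms": [m.n_atoms for m in mols],
            "n_heavy": [m.n_heavy for m in mols],
            "n_hydrogens": [m.n_hydrogens for m in mols],
            "molecular_weight": [m.molecular_weight for m in mols],
            "smiles": [m.smiles for m in mols],
            "valid": [m.valid for m in mols],
        }
    )
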