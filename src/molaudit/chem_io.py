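"""Reading/writing molecule sets and the validity/duplicate/connectivity filter.

Supported formats: multi-record XYZ (2-line header, coordinates in Å), SDF
(V2000, bond block preserved), and SMILES line files. Bond perception from
3D coordinates uses the covalent-radius criterion
``d(i,j) <= factor * (r_i + r_j)`` with a default factor of 1.3, the value
used for chemically diverse training sets; bond orders and aromaticity are
then assigned with RDKit's connectivity-based bond-order determination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdDetermineBonds

from .molecule import Molecule, connected_components, ensure_rdkit, from_rdkit, to_rdkit
from .periodic import COVALENT_RADII, covalent_radius

log = logging.getLogger(__name__)


@dataclass
class BondPerceptionParams:
    """Distance criterion for bonding two atoms from 3D coordinates."""

    covalent_radius_factor: float = 1.3
    radius_table: dict[str, float] = field(default_factory=lambda: dict(COVALENT_RADII))

    def __post_init__(self) -> None:
        if self.covalent_radius_factor <= 0:
            raise ValueError("covalent_radius_factor must be > 0")
        for el, r in self.radius_table.items():
            if r <= 0:
                raise ValueError(f"radius for {el} must be > 0")


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _parse_xyz(text: str, label: str, stem: str, errors: list[str]) -> list[Molecule]:
    lines = text.splitlines()
    mols: list[Molecule] = []
    pos, rec = 0, 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        rec += 1
        try:
            natoms = int(lines[pos].split()[0])
            body = lines[pos + 2 : pos + 2 + natoms]
            if len(body) < natoms:
                raise ValueError("truncated record")
            elements, coords = [], []
            for ln in body:
                parts = ln.split()
                elements.append(parts[0])
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            mols.append(
                Molecule(
                    id=f"{stem}-{rec}",
                    elements=elements,
                    coords=np.array(coords),
                    label=label,
                )
            )
            pos += 2 + natoms
        except (ValueError, IndexError) as exc:
            errors.append(f"record {rec}: {exc}")
            # resync: skip to the next line that looks like an atom count
            pos += 1
            while pos < len(lines):
                parts = lines[pos].split()
                if len(parts) == 1 and parts[0].isdigit():
                    break
                pos += 1
    return mols


def _read_sdf(path: Path, label: str, errors: list[str]) -> list[Molecule]:
    mols: list[Molecule] = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    for rec, raw in enumerate(supplier, start=1):
        if raw is None:
            errors.append(f"record {rec}: unparsable SDF block")
            continue
        mol_id = raw.GetProp("_Name").strip() if raw.HasProp("_Name") else ""
        mol_id = mol_id or f"{path.stem}-{rec}"
        try:
            clean = Chem.Mol(raw)
            Chem.SanitizeMol(clean)
            mols.append(from_rdkit(clean, mol_id, label))
        except Exception as exc:  # valence/aromaticity failure: keep, flag invalid
            try:
                m = from_rdkit_unsanitized(raw, mol_id, label)
                m.valid = False
                m.invalid_reason = str(exc)
                mols.append(m)
            except Exception as exc2:
                errors.append(f"record {rec}: {exc2}")
    return mols


def from_rdkit_unsanitized(raw: Chem.Mol, mol_id: str, label: str) -> Molecule:
    elements = [a.GetSymbol() for a in raw.GetAtoms()]
    coords = None
    if raw.GetNumConformers() > 0:
        coords = np.array(raw.GetConformer().GetPositions(), dtype=float)
    bonds = [
        (
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            max(int(round(b.GetBondTypeAsDouble())), 1),
            b.GetIsAromatic(),
        )
        for b in raw.GetBonds()
    ]
    return Molecule(
        id=mol_id, elements=elements, coords=coords, bonds=bonds,
        label=label, orders_assigned=True,
    )


def _read_smiles(path: Path, label: str, errors: list[str]) -> list[Molecule]:
    mols: list[Molecule] = []
    for rec, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smi = parts[0]
        mol_id = parts[1] if len(parts) > 1 else f"{path.stem}-{rec}"
        rd = Chem.MolFromSmiles(smi)
        if rd is None:
            errors.append(f"record {rec}: invalid SMILES {smi!r}")
            continue
        rd = Chem.AddHs(rd)
        mols.append(from_rdkit(rd, mol_id, label))
    return mols


def read_molecules(
    path: str | Path,
    format: str,
    label: str = "train",
    errors: Optional[list[str]] = None,
) -> list[Molecule]:
    """Read a molecule set from ``path``.

    Malformed records are collected into ``errors`` (and logged) and the run
    continues; an empty file (or a file yielding no molecules) raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    errs: list[str] = [] if errors is None else errors
    if format == "xyz":
        mols = _parse_xyz(path.read_text(), label, path.stem, errs)
    elif format == "sdf":
        mols = _read_sdf(path, label, errs)
    elif format == "smiles":
        mols = _read_smiles(path, label, errs)
    else:
        raise ValueError(f"unknown format {format!r}")
    for e in errs:
        log.warning("%s: %s", path.name, e)
    if not mols:
        raise ValueError(f"{path}: no molecules read ({len(errs)} bad records)")
    return mols


def write_xyz(mols: Sequence[Molecule], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in mols:
            if m.coords is None:
                raise ValueError(f"{m.id}: no coordinates to write")
            fh.write(f"{m.n_atoms}\n{m.id}\n")
            for el, (x, y, z) in zip(m.elements, m.coords):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def write_sdf(mols: Sequence[Molecule], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    for m in mols:
        rd = Chem.Mol(ensure_rdkit(m))
        rd.SetProp("_Name", m.id)
        writer.write(rd)
    writer.close()


def write_smiles(mols: Sequence[Molecule], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in mols:
            if m.smiles is None:
                raise ValueError(f"{m.id}: no SMILES to write")
            fh.write(f"{m.smiles} {m.id}\n")


# ---------------------------------------------------------------------------
# perception
# ---------------------------------------------------------------------------

def perceive_bonds(mol: Molecule, params: Optional[BondPerceptionParams] = None) -> Molecule:
    """Bond atoms i, j iff ``d(i,j) <= factor * (r_i + r_j)``.

    Orders are set to 1; order/aromaticity assignment is a separate step.
    """
    if mol.coords is None:
        raise ValueError(f"{mol.id}: coordinates required for bond perception")
    params = params or BondPerceptionParams()
    radii = np.array(
        [
            params.radius_table[e]
            if e in params.radius_table
            else covalent_radius(e)  # raises naming the symbol
            for e in mol.elements
        ]
    )
    diff = mol.coords[:, None, :] - mol.coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    thresh = params.covalent_radius_factor * (radii[:, None] + radii[None, :])
    ii, jj = np.where(np.triu(dist <= thresh, k=1))
    bonds = [(int(i), int(j), 1, False) for i, j in zip(ii, jj)]
    return mol.with_(bonds=bonds, orders_assigned=False, _rdmol=None)


def assign_bond_orders_and_aromaticity(mol: Molecule, charge: int = 0) -> Molecule:
    """Assign bond orders/aromatic flags and a canonical SMILES.

    Molecules whose perception fails (inconsistent valences, impossible
    geometry) are returned flagged invalid rather than raising, and are
    excluded from downstream analysis by :func:`filter_set`.
    """
    if not mol.bonds and mol.n_atoms > 1:
        raise ValueError(f"{mol.id}: bonds must be perceived first")
    try:
        if mol.orders_assigned:
            rd = to_rdkit(mol, sanitize=True)
        else:
            rd = to_rdkit(mol, sanitize=False)
            rdDetermineBonds.DetermineBondOrders(rd, charge=charge)
            Chem.SanitizeMol(rd)
        n_radical = sum(a.GetNumRadicalElectrons() for a in rd.GetAtoms())
        if n_radical > 0:
            raise ValueError(f"{n_radical} unpaired electrons after perception")
        out = from_rdkit(rd, mol.id, mol.label)
        out.coords = mol.coords
        return out
    except Exception as exc:
        return mol.with_(valid=False, invalid_reason=str(exc), _rdmol=None)


@dataclass
class FilterCounts:
    n_input: int = 0
    removed_disconnected: int = 0
    removed_invalid: int = 0
    removed_duplicate: int = 0

    @property
    def n_kept(self) -> int:
        return self.n_input - (
            self.removed_disconnected + self.removed_invalid + self.removed_duplicate
        )


def filter_set(mols: Sequence[Molecule]) -> tuple[list[Molecule], FilterCounts]:
    """Remove disconnected structures, perception-invalid molecules and
    canonical-SMILES duplicates (first occurrence kept), in input order."""
    counts = FilterCounts(n_input=len(mols))
    kept: list[Molecule] = []
    seen: set[str] = set()
    for m in mols:
        if connected_components(m) > 1:
            counts.removed_disconnected += 1
            continue
        if not m.valid or m.smiles is None:
            counts.removed_invalid += 1
            continue
        if m.smiles in seen:
            counts.removed_duplicate += 1
            continue
        seen.add(m.smiles)
        kept.append(m)
    return kept, counts
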