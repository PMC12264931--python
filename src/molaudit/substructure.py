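"""Functional-group prevalence and three-way ring classification.

Groups are SMARTS patterns (default catalog shipped with the package,
extensible via a two-column TSV). Rings use the smallest set of smallest
rings; a ring is *aromatic* iff all of its bonds are aromatic, *saturated*
iff it contains no multiple or aromatic bond, otherwise *unsaturated
aliphatic*. Only perception-valid molecules enter any denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from rdkit import Chem

from .molecule import Molecule, ensure_rdkit

RING_CLASSES = ("aromatic", "unsaturated_aliphatic", "saturated")


@dataclass
class GroupCatalog:
    """Named SMARTS patterns; every pattern is compiled at load time."""

    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("group names must be unique")
        self._compiled: dict[str, Chem.Mol] = {}
        for name, smarts in self.entries:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"SMARTS for {name!r} does not compile: {smarts!r}")
            self._compiled[name] = patt

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroupCatalog":
        entries = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, smarts = line.split("\t")
            entries.append((name, smarts))
        return cls(entries)

    @classmethod
    def default(cls) -> "GroupCatalog":
        with resources.as_file(
            resources.files("molaudit").joinpath("data/functional_groups.tsv")
        ) as p:
            return cls.from_tsv(p)

    def pattern(self, name: str) -> Chem.Mol:
        return self._compiled[name]

    def names(self) -> list[str]:
        return [n for n, _ in self.entries]


def group_prevalence(
    mols: Sequence[Molecule], catalog: Optional[GroupCatalog] = None
) -> pd.Series:
    """Fraction of (perception-valid) molecules containing >= 1 match per group."""
    catalog = catalog or GroupCatalog.default()
    valid = [m for m in mols if m.valid]
    if not valid:
        raise ValueError("no perception-valid molecules in set")
    hits = {name: 0 for name in catalog.names()}
    for m in valid:
        rd = ensure_rdkit(m)
        for name in hits:
            if rd.HasSubstructMatch(catalog.pattern(name)):
                hits[name] += 1
    out = pd.Series({n: c / len(valid) for n, c in hits.items()}, name="prevalence")
    out.index.name = "group"
    return out


def group_match_counts(mol: Molecule, catalog: GroupCatalog) -> dict[str, int]:
    """Number of (unique-atom-set) matches per group for one molecule."""
    rd = ensure_rdkit(mol)
    return {
        name: len(rd.GetSubstructMatches(catalog.pattern(name), uniquify=True))
        for name in catalog.names()
    }


def _classify_ring(rd: Chem.Mol, ring_atoms: tuple[int, ...]) -> str:
    ring = set(ring_atoms)
    arom, multiple = True, False
    for b in rd.GetBonds():
        if b.GetBeginAtomIdx() in ring and b.GetEndAtomIdx() in ring:
            if not b.GetIsAromatic():
                arom = False
            if b.GetIsAromatic() or b.GetBondTypeAsDouble() > 1.0:
                multiple = True
    if arom:
        return "aromatic"
    if multiple:
        return "unsaturated_aliphatic"
    return "saturated"


def ring_profile(mol: Molecule) -> dict:
    """Per-molecule SSSR ring counts by class and by ring size."""
    rd = ensure_rdkit(mol)
    rings = [tuple(r) for r in Chem.GetSymmSSSR(rd)]
    by_class = {c: 0 for c in RING_CLASSES}
    by_size: dict[int, int] = {}
    for r in rings:
        by_class[_classify_ring(rd, r)] += 1
        by_size[len(r)] = by_size.get(len(r), 0) + 1
    return {"id": mol.id, "total": len(rings), **by_class,
            **{f"size_{s}": c for s, c in sorted(by_size.items())}}


def ring_profiles(mols: Sequence[Molecule]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ring table per molecule plus the share of molecules having k rings of
    each class, k in {0, 1, 2, 3+}."""
    valid = [m for m in mols if m.valid]
    if not valid:
        raise ValueError("no perception-valid molecules in set")
    rows = [ring_profile(m) for m in valid]
    table = pd.DataFrame(rows).fillna(0)
    for col in table.columns:
        if col != "id":
            table[col] = table[col].astype(int)
    share_rows = {}
    for cls in RING_CLASSES:
        k = table[cls].clip(upper=3)
        share_rows[cls] = {
            "0": float((k == 0).mean()),
            "1": float((k == 1).mean()),
            "2": float((k == 2).mean()),
            "3+": float((k == 3).mean()),
        }
    share = pd.DataFrame(share_rows).T
    share.index.name = "ring_class"
    return table, share
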