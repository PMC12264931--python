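"""Composition, size, mass and geometry distributions, and the two-sample
tests (Welch's t, two-sample Kolmogorov-Smirnov) used to call a shift
between a training set and a generated set statistically significant.

Default binning: atom counts at width 1, molecular weight at 10 g/mol,
bonded distances at 0.02 Å over [0.8, 2.2] Å — fine enough to resolve the
single/double/triple C-C peaks near 1.54/1.33/1.20 Å.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .molecule import Molecule, pairwise_distance

log = logging.getLogger(__name__)

DISTANCE_EDGES = np.round(np.arange(0.8, 2.2 + 1e-9, 0.02), 10)


@dataclass
class Histogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    normalization: str = "counts"  # or "density"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("len(counts) must be len(bin_edges) - 1")

    @classmethod
    def from_samples(
        cls,
        samples: Sequence[float],
        bin_width: Optional[float] = None,
        edges: Optional[np.ndarray] = None,
    ) -> "Histogram":
        samples = np.asarray(samples, dtype=float)
        if edges is None:
            if bin_width is None:
                raise ValueError("give bin_width or edges")
            if samples.size == 0:
                edges = np.array([0.0, bin_width])
            else:
                lo = np.floor(samples.min() / bin_width) * bin_width
                hi = np.ceil(samples.max() / bin_width) * bin_width
                hi = hi + bin_width if hi <= lo else hi
                edges = np.arange(lo, hi + bin_width / 2, bin_width)
        counts, _ = np.histogram(samples, bins=edges)
        return cls(bin_edges=np.asarray(edges), counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def density(self) -> "Histogram":
        """Return the density-normalized form (integrates to 1)."""
        widths = np.diff(self.bin_edges)
        total = self.counts.sum()
        if total == 0:
            raise ValueError("cannot density-normalize an empty histogram")
        return Histogram(self.bin_edges, self.counts / (total * widths), "density")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
            }
        )


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: Optional[float]
    n_x: int
    n_y: int
    test: str

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "df": None if self.df is None else float(self.df),
            "n_x": self.n_x,
            "n_y": self.n_y,
        }


def elemental_composition(mols: Sequence[Molecule]) -> pd.Series:
    """Fraction of all atoms (hydrogens included) per element; sums to 1."""
    if not mols:
        raise ValueError("empty molecule set")
    counts: dict[str, int] = {}
    for m in mols:
        for e in m.elements:
            counts[e] = counts.get(e, 0) + 1
    total = sum(counts.values())
    frac = pd.Series({e: c / total for e, c in sorted(counts.items())}, name="fraction")
    frac.index.name = "element"
    return frac


@dataclass
class SizeMassSummary:
    atom_count: Histogram
    heavy_atom_count: Histogram
    molecular_weight: Histogram
    h_vs_total: list[tuple[int, int]]
    mean_atom_count: float
    mean_molecular_weight: float


def size_and_mass_distributions(
    mols: Sequence[Molecule],
    mw_bin_width: float = 10.0,
) -> SizeMassSummary:
    n_tot = [m.n_atoms for m in mols]
    n_heavy = [m.n_heavy for m in mols]
    mw = [m.molecular_weight for m in mols]
    h_vs_total = [(m.n_hydrogens, m.n_atoms) for m in mols]
    count_edges = np.arange(min(n_tot) - 0.5, max(n_tot) + 1.5, 1.0)
    heavy_edges = np.arange(min(n_heavy) - 0.5, max(n_heavy) + 1.5, 1.0)
    return SizeMassSummary(
        atom_count=Histogram.from_samples(n_tot, edges=count_edges),
        heavy_atom_count=Histogram.from_samples(n_heavy, edges=heavy_edges),
        molecular_weight=Histogram.from_samples(mw, bin_width=mw_bin_width),
        h_vs_total=h_vs_total,
        mean_atom_count=float(np.mean(n_tot)),
        mean_molecular_weight=float(np.mean(mw)),
    )


def bonded_distance_distribution(
    mols: Sequence[Molecule],
    elem_a: str,
    elem_b: str,
    edges: Optional[np.ndarray] = None,
) -> Histogram:
    """Histogram of perceived-bond distances between an (unordered) element pair."""
    edges = DISTANCE_EDGES if edges is None else np.asarray(edges, dtype=float)
    pair = frozenset((elem_a, elem_b)) if elem_a != elem_b else frozenset((elem_a,))
    dists: list[float] = []
    for m in mols:
        if m.coords is None:
            continue
        for i, j, _o, _a in m.bonds:
            if frozenset((m.elements[i], m.elements[j])) == pair:
                dists.append(pairwise_distance(m, i, j))
    if not dists:
        log.warning("no bonded %s-%s distances found", elem_a, elem_b)
    return Histogram.from_samples(dists, edges=edges)


def welch_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Welch's unequal-variance t test, two-sided, Welch-Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Welch's t needs at least 2 observations per sample")
    if np.var(x) == 0 and np.var(y) == 0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
        n_x=len(x),
        n_y=len(y),
        test="welch_t",
    )


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test, D = sup |ECDF_x - ECDF_y|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("KS needs at least 1 observation per sample")
    res = stats.ks_2samp(x, y)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=None,
        n_x=len(x),
        n_y=len(y),
        test="ks_2samp",
    )
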