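"""Corrective samplers: atom-count-matched downsampling and latent-space
grid flattening.

*Histogram matching* shrinks a generated set so its atom-count distribution
follows a reference (training) set: with reference bin probabilities p_b and
source availabilities a_b, the scale s = min_{p_b>0, a_b>0} a_b / p_b is the
largest feasible sample size preserving the reference shape, and each bin
contributes floor(s * p_b) molecules drawn uniformly without replacement.

*Grid flattening* balances a training set over the latent plane: the
bounding box of the first PCs is split into an n_grid x n_grid regular grid
and exactly one uniformly chosen molecule is kept per occupied rectangle.
The resolution is selected by flattening at each candidate n_grid, fitting a
KDE to the survivors and minimizing a spatial-localization score (the
coefficient of variation of the survivors' self-density); ties go to the
smallest candidate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .latent_space import gaussian_density, scott_bandwidth
from .molecule import Molecule


@dataclass
class ResamplePlan:
    """A replayable selection of indices into a molecule set."""

    indices: np.ndarray
    method: str  # histogram_match | grid_flatten
    params: dict
    seed: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("plan indices must be unique")

    def apply(self, mols: Sequence[Molecule]) -> list[Molecule]:
        return [mols[i] for i in self.indices]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "method": self.method,
                    "params": self.params,
                    "seed": self.seed,
                    "indices": self.indices.tolist(),
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ResamplePlan":
        d = json.loads(Path(path).read_text())
        return cls(
            indices=np.asarray(d["indices"]),
            method=d["method"],
            params=d["params"],
            seed=d["seed"],
        )


def atom_count_key(mol: Molecule) -> int:
    return mol.n_atoms


def downsample_to_histogram(
    source: Sequence[Molecule],
    reference: Sequence[Molecule],
    key: Callable[[Molecule], int] = atom_count_key,
    seed: int = 0,
) -> ResamplePlan:
    """Select source molecules so the key histogram matches the reference's
    shape at the largest feasible sample size."""
    if not source or not reference:
        raise ValueError("both sets must be non-empty")
    src_keys = np.array([key(m) for m in source])
    ref_keys = np.array([key(m) for m in reference])
    ref_bins, ref_counts = np.unique(ref_keys, return_counts=True)
    p = ref_counts / ref_counts.sum()
    avail = {b: np.flatnonzero(src_keys == b) for b in ref_bins}

    feasible = [(len(avail[b]) / pb) for b, pb in zip(ref_bins, p) if len(avail[b]) > 0]
    empty = [int(b) for b in ref_bins if len(avail[b]) == 0]
    if empty:
        warnings.warn(
            f"reference bins with no source molecules (quota 0): {empty}", stacklevel=2
        )
    if not feasible:
        raise ValueError("source covers none of the reference bins")
    s = min(feasible)

    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    quotas: dict[int, int] = {}
    for b, pb in zip(ref_bins, p):
        q = int(np.floor(s * pb)) if len(avail[b]) > 0 else 0
        q = min(q, len(avail[b]))
        quotas[int(b)] = q
        if q > 0:
            chosen.extend(rng.choice(avail[b], size=q, replace=False).tolist())
    chosen = sorted(chosen)
    return ResamplePlan(
        indices=np.asarray(chosen),
        method="histogram_match",
        params={"scale": float(s), "quotas": quotas, "key": "atom_count"},
        seed=seed,
    )


def grid_cell_assignment(points: np.ndarray, n_grid: int) -> np.ndarray:
    """Flat cell index per point on the n_grid x n_grid bounding-box grid."""
    points = np.asarray(points, dtype=float)
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    ij = np.floor((points - lo) / span * n_grid).astype(int)
    ij = np.clip(ij, 0, n_grid - 1)  # points on the max edge fall in the last cell
    return ij[:, 0] * n_grid + ij[:, 1]


def grid_flatten(points: np.ndarray, n_grid: int, seed: int = 0) -> ResamplePlan:
    """Retain exactly one uniformly chosen molecule per occupied grid cell."""
    points = np.asarray(points, dtype=float)
    if len(points) < 1:
        raise ValueError("at least one point required")
    if n_grid < 1:
        raise ValueError("n_grid must be >= 1")
    cells = grid_cell_assignment(points, n_grid)
    rng = np.random.default_rng(seed)
    chosen = []
    for cell in np.unique(cells):
        members = np.flatnonzero(cells == cell)
        chosen.append(int(rng.choice(members)))
    return ResamplePlan(
        indices=np.asarray(sorted(chosen)),
        method="grid_flatten",
        params={"n_grid": int(n_grid)},
        seed=seed,
    )


def localization_score(points: np.ndarray, bandwidth=None) -> float:
    """Coefficient of variation of the KDE self-density of a point cloud —
    0 for perfectly even coverage, large when the cloud is localized."""
    points = np.asarray(points, dtype=float)
    bw = np.asarray(bandwidth, float) if bandwidth is not None else scott_bandwidth(points)
    bw = np.where(bw <= 0, 1e-3, bw)
    dens = gaussian_density(points, points, bw)
    return float(dens.std() / dens.mean())


def select_n_grid(
    points: np.ndarray,
    candidates: Sequence[int],
    seed: int = 0,
    min_survivors: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Pick the grid resolution whose flattened set is least localized.

    Returns the chosen n_grid and the diagnostic curve
    (candidate, survivors, score). Ties go to the smallest candidate;
    candidates keeping fewer than ``min_survivors`` molecules are excluded.
    """
    if not candidates:
        raise ValueError("no candidates given")
    rows = []
    for cand in sorted(candidates):
        plan = grid_flatten(points, cand, seed=seed)
        surv = points[plan.indices]
        if len(surv) < min_survivors:
            warnings.warn(f"n_grid={cand} keeps only {len(surv)} molecules; excluded")
            rows.append({"n_grid": cand, "survivors": len(surv), "score": np.nan})
            continue
        rows.append(
            {"n_grid": cand, "survivors": len(surv), "score": localization_score(surv)}
        )
    curve = pd.DataFrame(rows)
    usable = curve.dropna(subset=["score"])
    if usable.empty:
        raise ValueError("no candidate kept enough molecules")
    best = int(usable.sort_values(["score", "n_grid"]).iloc[0]["n_grid"])
    return best, curve
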