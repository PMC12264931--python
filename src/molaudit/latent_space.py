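"""The 2D latent chemical space and its density/cluster machinery.

Two independent PCAs — one on the structural descriptor, one on the bonding
descriptor — are fit on the *concatenation* of the datasets under
comparison. Each molecule is mapped to (structural PC1 score, bonding PC1
score); that plane is the latent chemical space. A 2D Gaussian KDE locates
areas of localization, and a BIRCH-then-agglomerative hybrid clustering
groups molecules across datasets so that a cluster means the same chemistry
in either set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import AgglomerativeClustering, Birch
from sklearn.decomposition import PCA

from .descriptors import DescriptorMatrix


class DegenerateFitError(ValueError):
    pass


@dataclass
class LatentMap:
    """Fitted dual-PCA projection onto (structural PC1, bonding PC1)."""

    struct_mean: np.ndarray
    struct_components: np.ndarray        # (n_kept, d_struct)
    struct_evr: np.ndarray
    bond_mean: np.ndarray
    bond_components: np.ndarray
    bond_evr: np.ndarray
    struct_features: list[str]
    bond_features: list[str]
    n_fit: int = 0
    fit_population: str = "concatenation"

    @property
    def explained_variance_pc1(self) -> tuple[float, float]:
        return float(self.struct_evr[0]), float(self.bond_evr[0])


def _fit_pca(X: np.ndarray, n_components: int) -> PCA:
    if np.allclose(X.var(axis=0), 0.0):
        raise DegenerateFitError("all descriptor columns are constant")
    pca = PCA(n_components=min(n_components, min(X.shape) - 1) or 1)
    pca.fit(X)
    return pca


def fit_latent_map(
    pairs: Sequence[tuple[DescriptorMatrix, DescriptorMatrix]],
    n_components: int = 5,
) -> tuple[LatentMap, np.ndarray]:
    """Fit the dual PCA on concatenated (structural, bonding) descriptor pairs.

    Returns the fitted map and the latent points of the fit population,
    ordered as the concatenation of the input pairs.
    """
    if not pairs:
        raise ValueError("at least one (structural, bonding) pair required")
    struct = DescriptorMatrix.concat([p[0] for p in pairs])
    bond = DescriptorMatrix.concat([p[1] for p in pairs])
    if len(struct) != len(bond):
        raise ValueError("structural and bonding matrices disagree on molecule count")
    if len(struct) < 3:
        raise ValueError("need at least 3 molecules to fit the latent map")
    p_s = _fit_pca(struct.X, n_components)
    p_b = _fit_pca(bond.X, n_components)
    lmap = LatentMap(
        struct_mean=p_s.mean_,
        struct_components=p_s.components_,
        struct_evr=p_s.explained_variance_ratio_,
        bond_mean=p_b.mean_,
        bond_components=p_b.components_,
        bond_evr=p_b.explained_variance_ratio_,
        struct_features=list(struct.feature_names),
        bond_features=list(bond.feature_names),
        n_fit=len(struct),
    )
    return lmap, project(lmap, struct, bond)


def project(lmap: LatentMap, struct: DescriptorMatrix, bond: DescriptorMatrix) -> np.ndarray:
    """Affine projection with the stored means/loadings; no refit."""
    if struct.feature_names != lmap.struct_features:
        raise ValueError("structural feature registry does not match the fit")
    if bond.feature_names != lmap.bond_features:
        raise ValueError("bonding feature registry does not match the fit")
    s = (struct.X - lmap.struct_mean) @ lmap.struct_components[0]
    b = (bond.X - lmap.bond_mean) @ lmap.bond_components[0]
    return np.column_stack([s, b])


# ---------------------------------------------------------------------------
# kernel density estimation
# ---------------------------------------------------------------------------

def scott_bandwidth(points: np.ndarray) -> np.ndarray:
    """Scott's rule per axis: sigma_k * n^(-1/6) for 2D data."""
    n = len(points)
    return points.std(axis=0, ddof=1) * n ** (-1.0 / 6.0)


def gaussian_density(
    points: np.ndarray, eval_points: np.ndarray, bandwidth: np.ndarray
) -> np.ndarray:
    """Diagonal-bandwidth Gaussian KDE evaluated at arbitrary locations."""
    hx, hy = float(bandwidth[0]), float(bandwidth[1])
    dx = (eval_points[:, None, 0] - points[None, :, 0]) / hx
    dy = (eval_points[:, None, 1] - points[None, :, 1]) / hy
    k = np.exp(-0.5 * (dx**2 + dy**2))
    return k.sum(axis=1) / (len(points) * 2.0 * np.pi * hx * hy)


@dataclass
class DensitySurface:
    x_edges: np.ndarray  # grid node coordinates, length grid_size
    y_edges: np.ndarray
    density: np.ndarray  # (grid_size, grid_size), density[iy, ix]
    bandwidth: np.ndarray

    def integral(self) -> float:
        return float(
            np.trapezoid(np.trapezoid(self.density, self.x_edges, axis=1), self.y_edges)
        )

    def to_dict(self) -> dict:
        return {
            "x": self.x_edges.tolist(),
            "y": self.y_edges.tolist(),
            "density": self.density.tolist(),
            "bandwidth": self.bandwidth.tolist(),
        }


def kde2d(
    points: np.ndarray,
    bandwidth: Optional[Sequence[float]] = None,
    grid_size: int = 100,
    padding: float = 3.0,
) -> DensitySurface:
    """Gaussian-kernel density on a regular grid covering the data bounding
    box (padded by ``padding`` bandwidths so the grid captures the mass)."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("KDE needs at least 2 points")
    if np.allclose(points.std(axis=0), 0.0):
        raise ValueError("zero-variance point cloud")
    bw = np.asarray(bandwidth, dtype=float) if bandwidth is not None else scott_bandwidth(points)
    bw = np.where(bw <= 0, 1e-3, bw)
    lo = points.min(axis=0) - padding * bw
    hi = points.max(axis=0) + padding * bw
    xs = np.linspace(lo[0], hi[0], grid_size)
    ys = np.linspace(lo[1], hi[1], grid_size)
    gx, gy = np.meshgrid(xs, ys)
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    dens = gaussian_density(points, nodes, bw).reshape(grid_size, grid_size)
    return DensitySurface(x_edges=xs, y_edges=ys, density=dens, bandwidth=bw)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    labels: np.ndarray
    n_clusters: int
    birch_threshold: float
    sizes: dict[int, int] = field(default_factory=dict)
    centroids: dict[int, tuple[float, float]] = field(default_factory=dict)


def cluster_latent(
    points: np.ndarray,
    n_clusters: int = 25,
    birch_threshold: Optional[float] = None,
    min_subcluster_factor: int = 4,
) -> ClusterAssignment:
    """BIRCH subclustering followed by agglomerative merging to ``n_clusters``.

    The BIRCH threshold is lowered until the subcluster stage yields at
    least ``min_subcluster_factor`` times the requested cluster count, so the
    agglomerative stage has material to merge clusters of different sizes.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < n_clusters:
        raise ValueError(f"{len(points)} points < {n_clusters} clusters")
    if birch_threshold is None:
        threshold = 0.5 * float(points.std(axis=0).mean() or 1.0)
        for _ in range(12):
            probe = Birch(threshold=threshold, n_clusters=None)
            probe.fit(points)
            if len(probe.subcluster_centers_) >= min_subcluster_factor * n_clusters:
                break
            threshold /= 2.0
        birch_threshold = threshold
    birch = Birch(
        threshold=birch_threshold,
        n_clusters=AgglomerativeClustering(n_clusters=n_clusters),
    )
    labels = birch.fit_predict(points)
    sizes = {int(k): int((labels == k).sum()) for k in np.unique(labels)}
    centroids = {
        int(k): tuple(points[labels == k].mean(axis=0).round(6)) for k in np.unique(labels)
    }
    return ClusterAssignment(
        labels=labels,
        n_clusters=int(len(np.unique(labels))),
        birch_threshold=float(birch_threshold),
        sizes=sizes,
        centroids=centroids,
    )
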