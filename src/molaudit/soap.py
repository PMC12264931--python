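"""Averaged SOAP-style structural descriptor.

Each atom's neighborhood is represented as a sum of Gaussians of width
``sigma`` placed on every atom (the central atom included) within a cutoff,
one density channel per chemical species. The density is expanded in an
orthonormal polynomial radial basis g_n(r) and spherical harmonics Y_lm, and
the rotation-invariant power spectrum

    p^{Z1,Z2}_{n1 n2 l} = pi * sqrt(8 / (2l + 1)) * sum_m c^{Z1}_{n1 l m} conj(c^{Z2}_{n2 l m})

is averaged over all atoms of the molecule. The result is invariant to
rigid rotation, translation, and atom reindexing, and is additive over
fragments separated by more than the cutoff.

Expansion coefficients are computed analytically from the plane-wave-like
expansion of an off-center Gaussian,

    exp(-a|r - R|^2) = 4 pi exp(-a(r^2 + R^2)) sum_lm i_l(2 a r R) Y_lm(rhat) Y*_lm(Rhat),

with the remaining radial integral done by fixed Gauss-Legendre quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.special import sph_harm_y, spherical_in

from .molecule import Molecule

_QUAD_POINTS = 64


@dataclass
class StructuralDescriptorConfig:
    cutoff: float = 5.0          # Å
    n_radial: int = 8
    l_max: int = 6
    sigma: float = 0.3           # Å, Gaussian width of the atomic density
    species: tuple[str, ...] = ("H", "C", "N", "O", "F", "S", "Cl")

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.n_radial < 1 or self.l_max < 0 or self.sigma <= 0:
            raise ValueError("invalid structural descriptor configuration")
        self.species = tuple(self.species)

    @property
    def n_features(self) -> int:
        s = len(self.species)
        same = self.n_radial * (self.n_radial + 1) // 2
        cross = self.n_radial * self.n_radial
        n_pairs_same = s
        n_pairs_cross = s * (s - 1) // 2
        return (n_pairs_same * same + n_pairs_cross * cross) * (self.l_max + 1)

    def feature_names(self) -> list[str]:
        names = []
        s = self.species
        for a in range(len(s)):
            for b in range(a, len(s)):
                for n1 in range(self.n_radial):
                    n2_start = n1 if a == b else 0
                    for n2 in range(n2_start, self.n_radial):
                        for l in range(self.l_max + 1):
                            names.append(f"p[{s[a]},{s[b]}][n{n1},n{n2}][l{l}]")
        return names


def radial_basis(cfg: StructuralDescriptorConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal polynomial radial basis on Gauss-Legendre nodes.

    Returns (nodes, quadrature weights, basis values g[n, node]) with
    ``integral g_n(r) g_m(r) r^2 dr = delta_nm`` on [0, cutoff].
    """
    x, w = np.polynomial.legendre.leggauss(_QUAD_POINTS)
    r = 0.5 * cfg.cutoff * (x + 1.0)
    wr = 0.5 * cfg.cutoff * w
    # phi_n(r) = (cutoff - r)^(n+2), n = 0..n_radial-1
    phi = np.stack([(cfg.cutoff - r) ** (n + 2) for n in range(cfg.n_radial)])
    S = (phi * wr * r**2) @ phi.T
    evals, evecs = np.linalg.eigh(S)
    S_inv_sqrt = evecs @ np.diag(evals**-0.5) @ evecs.T
    g = S_inv_sqrt @ phi
    return r, wr, g


def _center_coefficients(
    rel: np.ndarray, cfg: StructuralDescriptorConfig,
    r: np.ndarray, wr: np.ndarray, g: np.ndarray,
) -> np.ndarray:
    """Expansion coefficients c[n, l, m+l] of one species channel around one
    center; ``rel`` holds neighbor positions relative to the center."""
    a = 1.0 / (2.0 * cfg.sigma**2)
    n_max, l_max = cfg.n_radial, cfg.l_max
    c = np.zeros((n_max, l_max + 1, 2 * l_max + 1), dtype=complex)
    if len(rel) == 0:
        return c
    R = np.linalg.norm(rel, axis=1)
    integrand = np.exp(-a * r**2) * wr * r**2

    on_center = R < 1e-12
    if on_center.any():
        # on-center Gaussian: only l = 0 survives (i_l(0) = delta_l0)
        radint = g @ integrand
        c[:, 0, 0] += (
            on_center.sum() * 4.0 * np.pi * radint * (0.5 / np.sqrt(np.pi))
        )
    rel = rel[~on_center]
    R = R[~on_center]
    if len(R) == 0:
        return c

    theta = np.arccos(np.clip(rel[:, 2] / R, -1.0, 1.0))
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    damp = np.exp(-a * R**2)
    ells = np.arange(l_max + 1)
    # i_l(2 a r R_j): (l, neighbor, node)
    bessel = spherical_in(
        ells[:, None, None], 2.0 * a * R[None, :, None] * r[None, None, :]
    )
    # radial integrals I[n, l, j]
    I = np.einsum("nq,ljq,q->nlj", g, bessel, integrand)
    for l in range(l_max + 1):
        m = np.arange(-l, l + 1)
        ylm = sph_harm_y(l, m[None, :], theta[:, None], phi[:, None])  # (j, m)
        c[:, l, : 2 * l + 1] = (
            c[:, l, : 2 * l + 1]
            + 4.0 * np.pi * np.einsum("j,nj,jm->nm", damp, I[:, l, :], np.conj(ylm))
        )
    return c


def structural_descriptor(mol: Molecule, cfg: StructuralDescriptorConfig) -> np.ndarray:
    """Averaged power-spectrum descriptor of one molecule."""
    if mol.coords is None:
        raise ValueError(f"{mol.id}: coordinates required")
    unknown = set(mol.elements) - set(cfg.species)
    if unknown:
        raise ValueError(f"{mol.id}: elements outside species list: {sorted(unknown)}")
    r, wr, g = radial_basis(cfg)
    coords = mol.coords
    elements = np.array(mol.elements)
    n_max, l_max = cfg.n_radial, cfg.l_max
    nsp = len(cfg.species)

    # flat index arrays in feature_names() order
    a_idx, b_idx, n1_idx, n2_idx, l_idx = [], [], [], [], []
    for a_i in range(nsp):
        for b_i in range(a_i, nsp):
            for n1 in range(n_max):
                for n2 in range(n1 if a_i == b_i else 0, n_max):
                    for l in range(l_max + 1):
                        a_idx.append(a_i)
                        b_idx.append(b_i)
                        n1_idx.append(n1)
                        n2_idx.append(n2)
                        l_idx.append(l)
    a_idx, b_idx = np.array(a_idx), np.array(b_idx)
    n1_idx, n2_idx, l_idx = np.array(n1_idx), np.array(n2_idx), np.array(l_idx)
    prefac = np.pi * np.sqrt(8.0 / (2 * l_idx + 1))

    acc = np.zeros(cfg.n_features)
    for i in range(mol.n_atoms):
        rel_all = coords - coords[i]
        dist = np.linalg.norm(rel_all, axis=1)
        inside = dist <= cfg.cutoff
        C = np.stack(
            [
                _center_coefficients(rel_all[inside & (elements == sp)], cfg, r, wr, g)
                for sp in cfg.species
            ]
        )  # (nsp, n_max, l_max+1, 2*l_max+1)
        P = np.einsum("anlm,bklm->abnkl", C, np.conj(C)).real
        acc += prefac * P[a_idx, b_idx, n1_idx, n2_idx, l_idx]
    return acc / mol.n_atoms
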