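"""Structural (SOAP-style), bonding, and fingerprint descriptors."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from molaudit.chem_io import assign_bond_orders_and_aromaticity, perceive_bonds
from molaudit.descriptors import (
    BondingDescriptorSchema,
    DescriptorMatrix,
    FingerprintConfig,
    bonding_descriptor,
    circular_fingerprint,
    featurize_set,
)
from molaudit.molecule import Molecule
from molaudit.soap import StructuralDescriptorConfig, radial_basis, structural_descriptor

SMALL_CFG = StructuralDescriptorConfig(cutoff=4.0, n_radial=4, l_max=3,
                                       species=("H", "C", "N", "O"))


class TestStructural:
    def test_rigid_motion_invariance(self, ethanol):
        v = structural_descriptor(ethanol, SMALL_CFG)
        R = Rotation.from_euler("xyz", [0.4, -1.2, 2.2]).as_matrix()
        moved = ethanol.with_(coords=ethanol.coords @ R.T + np.array([5.0, -3.0, 1.0]))
        assert np.abs(v - structural_descriptor(moved, SMALL_CFG)).max() < 1e-8

    def test_reindex_invariance(self, water):
        cfg = StructuralDescriptorConfig(cutoff=4.0, n_radial=4, l_max=3,
                                         species=("H", "O"))
        v = structural_descriptor(water, cfg)
        permuted = Molecule("w", ["H", "O", "H"], coords=water.coords[[1, 0, 2]])
        assert np.abs(v - structural_descriptor(permuted, cfg)).max() < 1e-12

    def test_single_atom_closed_form(self):
        """Isolated atom: only the on-center Gaussian contributes, so all
        l > 0 channels vanish and the l = 0 channel follows from the radial
        integral of g_n(r) e^{-r^2 / 2 sigma^2}, done here with an
        independent quadrature."""
        cfg = StructuralDescriptorConfig(cutoff=4.0, n_radial=3, l_max=2, species=("C",))
        atom = Molecule("c", ["C"], coords=np.zeros((1, 3)))
        v = structural_descriptor(atom, cfg)
        from scipy.integrate import quad

        # independent radial basis: phi_n = (rc - r)^(n+2) orthonormalized
        # with the analytic overlap  S_nm = 2 rc^(n+m+7) / ((n+m+5)(n+m+6)(n+m+7))
        rc = cfg.cutoff
        nmax = cfg.n_radial
        S = np.empty((nmax, nmax))
        for n in range(nmax):
            for m in range(nmax):
                p = n + m + 4
                S[n, m] = 2.0 * rc ** (p + 3) / ((p + 1) * (p + 2) * (p + 3))
        evals, evecs = np.linalg.eigh(S)
        S_inv_sqrt = evecs @ np.diag(evals**-0.5) @ evecs.T

        a = 1.0 / (2.0 * cfg.sigma**2)
        c_n = []
        for n in range(nmax):
            integrand = lambda rr, n=n: sum(
                S_inv_sqrt[n, m] * (rc - rr) ** (m + 2) for m in range(nmax)
            ) * np.exp(-a * rr**2) * rr**2
            val, _err = quad(integrand, 0.0, rc, limit=200)
            c_n.append(np.sqrt(4.0 * np.pi) * val)
        expected = []
        for n1 in range(cfg.n_radial):
            for n2 in range(n1, cfg.n_radial):
                for l in range(cfg.l_max + 1):
                    expected.append(
                        np.pi * np.sqrt(8.0 / (2 * l + 1)) * (c_n[n1] * c_n[n2])
                        if l == 0 else 0.0
                    )
        assert np.abs(v - np.array(expected)).max() < 1e-6

    def test_dimer_additivity_beyond_cutoff(self):
        frag = np.array([[0.0, 0, 0], [1.1, 0, 0]])
        far = frag + np.array([3.0 * SMALL_CFG.cutoff, 0, 0])
        mono_a = Molecule("a", ["C", "O"], coords=frag)
        mono_b = Molecule("b", ["C", "O"], coords=far)
        dimer = Molecule("ab", ["C", "O", "C", "O"], coords=np.vstack([frag, far]))
        va = structural_descriptor(mono_a, SMALL_CFG)
        vb = structural_descriptor(mono_b, SMALL_CFG)
        vab = structural_descriptor(dimer, SMALL_CFG)
        assert np.abs(vab - 0.5 * (va + vb)).max() < 1e-10

    def test_element_outside_species_raises(self, water):
        with pytest.raises(ValueError, match="O"):
            structural_descriptor(water, StructuralDescriptorConfig(species=("H", "C")))

    def test_feature_count_matches_registry(self, ethanol):
        v = structural_descriptor(ethanol, SMALL_CFG)
        assert len(v) == SMALL_CFG.n_features == len(SMALL_CFG.feature_names())


class TestBonding:
    def test_methane_counts(self, methane):
        m = assign_bond_orders_and_aromaticity(methane)
        schema = BondingDescriptorSchema(species=("H", "C", "N", "O", "F", "S", "Cl"))
        v = bonding_descriptor(m, schema)
        names = schema.feature_names
        assert v[names.index("n_C")] == 1
        assert v[names.index("n_H")] == 4
        assert v[names.index("bond_single[H,C]")] == 4
        assert v[names.index("molecular_weight")] == pytest.approx(16.043, abs=0.01)
        assert v[names.index("h_fraction")] == pytest.approx(0.8)

    def test_benzene_aromatic_ring_feature(self, benzene):
        m = assign_bond_orders_and_aromaticity(perceive_bonds(benzene))
        schema = BondingDescriptorSchema()
        v = bonding_descriptor(m, schema)
        assert v[schema.feature_names.index("ring_aromatic_size6")] == 1
        assert v[schema.feature_names.index("bond_aromatic[C,C]")] == 6

    def test_group_features_match_substructure_module(self, small_set):
        """Cross-module consistency: group_* features equal the substructure
        module's match counts."""
        from molaudit.substructure import GroupCatalog, group_match_counts

        schema = BondingDescriptorSchema()
        cat = GroupCatalog.default()
        for m in small_set[:25]:
            v = bonding_descriptor(m, schema)
            counts = group_match_counts(m, cat)
            for g, cnt in counts.items():
                assert v[schema.feature_names.index(f"group_{g}")] == cnt

    def test_entries_non_negative(self, small_set):
        schema = BondingDescriptorSchema()
        X = np.stack([bonding_descriptor(m, schema) for m in small_set[:50]])
        assert (X >= 0).all()

    def test_reindex_invariance(self, cyclohexene):
        m = cyclohexene
        rng = np.random.default_rng(1)
        perm = rng.permutation(m.n_atoms)
        inv = np.argsort(perm)
        permuted = Molecule(
            "perm", [m.elements[i] for i in perm], coords=m.coords[perm],
            bonds=[(int(inv[i]), int(inv[j]), o, a) for i, j, o, a in m.bonds],
            orders_assigned=True,
        )
        schema = BondingDescriptorSchema()
        assert np.array_equal(bonding_descriptor(m, schema),
                              bonding_descriptor(permuted, schema))


class TestFingerprint:
    def test_identical_molecules_identical_fingerprints(self, ethanol):
        cfg = FingerprintConfig()
        assert np.array_equal(
            circular_fingerprint(ethanol, cfg),
            circular_fingerprint(ethanol.with_(id="copy"), cfg),
        )

    def test_methane_ethane_differ(self, methane, ethane):
        m1 = assign_bond_orders_and_aromaticity(methane)
        cfg = FingerprintConfig(radius=1, n_bits=1024, augment_counts=False)
        assert not np.array_equal(
            circular_fingerprint(m1, cfg), circular_fingerprint(ethane, cfg)
        )

    def test_augmentation_appends_element_counts(self, ethanol):
        species = ("H", "C", "N", "O")
        plain = circular_fingerprint(
            ethanol, FingerprintConfig(augment_counts=False), species
        )
        aug = circular_fingerprint(
            ethanol, FingerprintConfig(augment_counts=True), species
        )
        assert len(aug) == len(plain) + len(species) + 1
        assert aug[len(plain)] == ethanol.n_heavy
        assert list(aug[len(plain) + 1:]) == [
            sum(1 for e in ethanol.elements if e == sp) for sp in species
        ]

    def test_n_bits_must_be_power_of_two(self):
        with pytest.raises(ValueError):
            FingerprintConfig(n_bits=1000)


class TestDescriptorMatrix:
    def test_concat_requires_matching_registry(self, small_set):
        a = featurize_set(small_set[:5], "bonding")
        b = featurize_set(small_set[5:10], "bonding")
        both = DescriptorMatrix.concat([a, b])
        assert len(both) == 10
        c = DescriptorMatrix(np.zeros((2, 3)), ["x", "y", "z"])
        with pytest.raises(ValueError):
            DescriptorMatrix.concat([a, c])
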