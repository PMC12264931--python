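"""IO, covalent-radius bond perception, order assignment and the set filter."""

import numpy as np
import pytest

from molaudit.chem_io import (
    BondPerceptionParams,
    assign_bond_orders_and_aromaticity,
    filter_set,
    perceive_bonds,
    read_molecules,
    write_sdf,
    write_xyz,
)
from molaudit.molecule import Molecule

H2_074 = Molecule("h2", ["H", "H"], coords=[[0, 0, 0], [0.74, 0, 0]])


class TestReadWrite:
    def test_minimal_xyz_record(self, tmp_path):
        p = tmp_path / "h2.xyz"
        p.write_text("2\nhydrogen\nH 0.0 0.0 0.0\nH 0.74 0.0 0.0\n")
        mols = read_molecules(p, "xyz")
        assert len(mols) == 1
        assert mols[0].elements == ["H", "H"]
        assert mols[0].bonds == []
        assert np.allclose(mols[0].coords[1], [0.74, 0, 0])

    def test_xyz_round_trip_preserves_geometry(self, tmp_path, ethanol, methane):
        p = tmp_path / "set.xyz"
        write_xyz([ethanol, methane], p)
        back = read_molecules(p, "xyz")
        assert [m.elements for m in back] == [ethanol.elements, methane.elements]
        for orig, rt in zip([ethanol, methane], back):
            assert np.abs(orig.coords - rt.coords).max() < 1e-4

    def test_sdf_round_trip_preserves_bond_orders(self, tmp_path, ethanol):
        p = tmp_path / "ethanol.sdf"
        write_sdf([ethanol], p)
        back = read_molecules(p, "sdf")
        assert len(back) == 1
        m = back[0]
        assert m.elements == ethanol.elements
        assert np.abs(m.coords - ethanol.coords).max() < 1e-4
        assert sorted((i, j, o) for i, j, o, _ in m.bonds) == sorted(
            (i, j, o) for i, j, o, _ in ethanol.bonds
        )
        assert m.smiles == ethanol.smiles

    def test_malformed_xyz_record_collected(self, tmp_path):
        p = tmp_path / "mixed.xyz"
        p.write_text(
            "2\nok\nH 0 0 0\nH 0.74 0 0\n"
            "3\nbad\nH 0 0 zzz\nH 1 0 0\nH 2 0 0\n"
            "2\nok2\nO 0 0 0\nO 1.2 0 0\n"
        )
        errors: list[str] = []
        mols = read_molecules(p, "xyz", errors=errors)
        assert len(mols) == 2
        assert len(errors) == 1

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "empty.xyz"
        p.write_text("")
        with pytest.raises(ValueError):
            read_molecules(p, "xyz")

    def test_smiles_input_gets_explicit_hydrogens(self, tmp_path):
        p = tmp_path / "mols.smi"
        p.write_text("CCO ethanol\nC methane\n")
        mols = read_molecules(p, "smiles")
        assert mols[0].n_atoms == 9 and mols[0].n_hydrogens == 6
        assert mols[1].n_atoms == 5


class TestPerceiveBonds:
    def test_h2_bonded_at_074(self):
        # threshold 1.3 * (0.31 + 0.31) = 0.806 Å
        m = perceive_bonds(H2_074)
        assert m.bonds == [(0, 1, 1, False)]

    def test_h2_unbonded_at_100(self):
        m = perceive_bonds(Molecule("h2", ["H", "H"], coords=[[0, 0, 0], [1.0, 0, 0]]))
        assert m.bonds == []

    def test_default_factor_is_13(self):
        assert BondPerceptionParams().covalent_radius_factor == 1.3

    def test_unknown_element_named_in_error(self):
        m = Molecule("x", ["C", "Og"], coords=[[0, 0, 0], [1.5, 0, 0]])
        with pytest.raises(ValueError, match="Og"):
            perceive_bonds(m)

    @pytest.mark.parametrize("angles", [(0.3, 1.1, -0.7), (2.0, 0.2, 0.9)])
    def test_rigid_motion_invariance(self, ethanol, angles):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", angles).as_matrix()
        moved = ethanol.with_(coords=ethanol.coords @ R.T + np.array([3.0, -1.0, 2.0]))
        a = perceive_bonds(ethanol)
        b = perceive_bonds(moved)
        assert a.bonds == b.bonds

    def test_symmetric_in_atom_order(self, water):
        perm = [2, 0, 1]
        permuted = Molecule("w", [water.elements[i] for i in perm], coords=water.coords[perm])
        inv = {old: new for new, old in enumerate(perm)}
        expected = sorted(
            (min(inv[i], inv[j]), max(inv[i], inv[j])) for i, j, _o, _a in
            perceive_bonds(water.with_(bonds=[], orders_assigned=False)).bonds
        )
        got = sorted((i, j) for i, j, _o, _a in perceive_bonds(permuted).bonds)
        assert got == expected


class TestAssignOrders:
    def test_benzene_gets_six_aromatic_cc_bonds(self, benzene):
        m = assign_bond_orders_and_aromaticity(perceive_bonds(benzene))
        assert m.valid
        arom_cc = [
            b for b in m.bonds
            if b[3] and m.elements[b[0]] == "C" and m.elements[b[1]] == "C"
        ]
        assert len(arom_cc) == 6

    def test_ethyne_gets_triple_bond(self, ethyne):
        m = assign_bond_orders_and_aromaticity(perceive_bonds(ethyne))
        assert m.valid
        cc = [b for b in m.bonds if m.elements[b[0]] == m.elements[b[1]] == "C"]
        assert cc[0][2] == 3

    def test_degenerate_geometry_flagged_invalid(self):
        m = Molecule("bad", ["C", "C"], coords=[[0, 0, 0], [0.3, 0, 0]])
        out = assign_bond_orders_and_aromaticity(perceive_bonds(m))
        assert not out.valid
        assert out.invalid_reason


class TestFilterSet:
    def _prep(self, mols):
        return [assign_bond_orders_and_aromaticity(m) for m in mols]

    def test_duplicates_removed_first_kept(self, ethanol, methane):
        dup = ethanol.with_(id="ethanol2")
        methane = assign_bond_orders_and_aromaticity(methane)
        kept, counts = filter_set([ethanol, dup, methane])
        assert [m.id for m in kept] == ["ethanol", "methane"]
        assert counts.removed_duplicate == 1

    def test_disconnected_removed(self, methane):
        two = Molecule(
            "2xch4",
            methane.elements * 2,
            coords=np.vstack([methane.coords, methane.coords + 10.0]),
        )
        two = assign_bond_orders_and_aromaticity(perceive_bonds(two))
        methane = assign_bond_orders_and_aromaticity(methane)
        kept, counts = filter_set([two, methane])
        assert [m.id for m in kept] == ["methane"]
        assert counts.removed_disconnected == 1

    def test_invalid_removed(self, methane):
        bad = Molecule("bad", ["C", "C"], coords=[[0, 0, 0], [0.3, 0, 0]])
        bad = assign_bond_orders_and_aromaticity(perceive_bonds(bad))
        methane = assign_bond_orders_and_aromaticity(methane)
        kept, counts = filter_set([bad, methane])
        assert counts.removed_invalid == 1
        assert [m.id for m in kept] == ["methane"]

    def test_idempotent_and_output_smiles_unique(self, medium_set):
        once, counts1 = filter_set(medium_set)
        twice, counts2 = filter_set(once)
        assert [m.id for m in once] == [m.id for m in twice]
        assert counts2.removed_duplicate == counts2.removed_invalid == 0
        smiles = [m.smiles for m in once]
        assert len(smiles) == len(set(smiles))

    def test_survivor_count_matches_brute_force(self, small_set):
        """Independent re-implementation of the three filter rules."""
        import networkx as nx
        from rdkit import Chem

        def brute(mols):
            survivors, seen = [], set()
            for m in mols:
                g = nx.Graph()
                g.add_nodes_from(range(m.n_atoms))
                g.add_edges_from((i, j) for i, j, _o, _a in m.bonds)
                if nx.number_connected_components(g) > 1:
                    continue
                if not m.valid or m.smiles is None:
                    continue
                key = Chem.CanonSmiles(m.smiles)
                if key in seen:
                    continue
                seen.add(key)
                survivors.append(m.id)
            return survivors

        kept, _ = filter_set(small_set)
        assert [m.id for m in kept] == brute(small_set)
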