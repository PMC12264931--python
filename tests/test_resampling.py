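"""Histogram-matched downsampling and latent-grid flattening."""

import numpy as np
import pytest

from molaudit.dataset_stats import ks_two_sample
from molaudit.molecule import Molecule
from molaudit.resampling import (
    ResamplePlan,
    downsample_to_histogram,
    grid_cell_assignment,
    grid_flatten,
    localization_score,
    select_n_grid,
)


def _mols_with_atom_counts(counts):
    return [
        Molecule(f"m{k}", ["C"] * c, bonds=[], orders_assigned=True)
        for k, c in enumerate(counts)
    ]


class TestDownsample:
    def test_hand_quota_example(self):
        # reference {5:1, 10:1}; source 4 molecules at 5 and 2 at 10
        # -> s = min(4/0.5, 2/0.5) = 4, quotas floor(4*0.5) = 2 and 2
        ref = _mols_with_atom_counts([5, 10])
        src = _mols_with_atom_counts([5, 5, 5, 5, 10, 10])
        plan = downsample_to_histogram(src, ref, seed=1)
        keys = sorted(src[i].n_atoms for i in plan.indices)
        assert keys == [5, 5, 10, 10]

    def test_proportional_source_fully_selected(self):
        ref = _mols_with_atom_counts([5, 5, 10])
        src = _mols_with_atom_counts([5, 5, 5, 5, 10, 10])
        plan = downsample_to_histogram(src, ref, seed=0)
        assert sorted(plan.indices.tolist()) == list(range(6))

    def test_uncovered_reference_bin_warns_with_zero_quota(self):
        ref = _mols_with_atom_counts([5, 10])
        src = _mols_with_atom_counts([5, 5])
        with pytest.warns(UserWarning, match="10"):
            plan = downsample_to_histogram(src, ref, seed=0)
        assert plan.params["quotas"][10] == 0

    def test_per_bin_deviation_at_most_one_from_scaled_reference(self, medium_set, base_config):
        from molaudit.synthetic import bias_config, generate_molecule_set

        gen = generate_molecule_set(bias_config(base_config, 0.7), 400, seed=31,
                                    label="generated")
        plan = downsample_to_histogram(gen, medium_set, seed=5)
        kept_keys = np.array([gen[i].n_atoms for i in plan.indices])
        ref_keys = np.array([m.n_atoms for m in medium_set])
        s = plan.params["scale"]
        for b in np.unique(ref_keys):
            expected = s * np.mean(ref_keys == b) * 1.0
            got = np.sum(kept_keys == b)
            # floor(quota) plus possible zero-availability bins
            assert got <= expected + 1e-9
            if got > 0:
                assert expected - got <= 1.0 + 1e-9

    def test_ks_distance_not_increased(self, medium_set, base_config):
        from molaudit.synthetic import bias_config, generate_molecule_set

        gen = generate_molecule_set(bias_config(base_config, 0.8), 400, seed=37,
                                    label="generated")
        # bias the size distribution of the source so there is something to fix
        gen = [m for m in gen if m.n_atoms >= 18] + [m for m in gen if m.n_atoms < 18][:120]
        plan = downsample_to_histogram(gen, medium_set, seed=6)
        ref = [m.n_atoms for m in medium_set]
        before = ks_two_sample([m.n_atoms for m in gen], ref).statistic
        after = ks_two_sample([gen[i].n_atoms for i in plan.indices], ref).statistic
        assert after <= before

    def test_deterministic_and_replayable(self, tmp_path, medium_set, base_config):
        from molaudit.synthetic import bias_config, generate_molecule_set

        gen = generate_molecule_set(bias_config(base_config, 0.5), 300, seed=41)
        p1 = downsample_to_histogram(gen, medium_set, seed=9)
        p2 = downsample_to_histogram(gen, medium_set, seed=9)
        assert np.array_equal(p1.indices, p2.indices)
        f = tmp_path / "plan.json"
        p1.to_json(f)
        replay = ResamplePlan.from_json(f)
        assert np.array_equal(replay.indices, p1.indices)
        assert replay.method == "histogram_match"

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            downsample_to_histogram([], _mols_with_atom_counts([5]), seed=0)


class TestGridFlatten:
    def test_distinct_cells_all_retained(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
        plan = grid_flatten(pts, n_grid=2, seed=0)
        assert sorted(plan.indices.tolist()) == [0, 1, 2, 3]

    def test_single_cell_keeps_exactly_one(self):
        pts = np.tile([[1.0, 1.0]], (10, 1)) + 1e-9 * np.arange(10)[:, None]
        plan = grid_flatten(pts, n_grid=1, seed=3)
        assert len(plan.indices) == 1

    def test_occupancy_matches_brute_force(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(300, 2))
        n_grid = 7
        plan = grid_flatten(pts, n_grid, seed=2)
        # independent exhaustive binning
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        occupied = set()
        for p in pts:
            ix = min(int((p[0] - lo[0]) / (hi[0] - lo[0]) * n_grid), n_grid - 1)
            iy = min(int((p[1] - lo[1]) / (hi[1] - lo[1]) * n_grid), n_grid - 1)
            occupied.add((ix, iy))
        assert len(plan.indices) == len(occupied)
        # one survivor per occupied cell
        cells = grid_cell_assignment(pts, n_grid)
        assert sorted(set(cells[plan.indices])) == sorted(set(cells))
        assert len(set(cells[plan.indices])) == len(plan.indices)

    def test_replay_bit_exact(self, tmp_path):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(200, 2))
        plan = grid_flatten(pts, 9, seed=77)
        f = tmp_path / "flat.json"
        plan.to_json(f)
        replay = ResamplePlan.from_json(f)
        assert np.array_equal(replay.indices, plan.indices)
        assert np.array_equal(grid_flatten(pts, 9, seed=77).indices, plan.indices)


class TestSelectNGrid:
    def test_identical_survivor_sets_tie_to_smallest(self):
        # four far-apart points: both grids put each point in its own cell
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
        pts = np.repeat(pts, 4, axis=0) + 1e-6 * np.arange(16)[:, None]
        best, curve = select_n_grid(pts, [2, 4], seed=0, min_survivors=2)
        assert best == 2

    def test_flattening_bimodal_cloud_reduces_localization(self):
        rng = np.random.default_rng(21)
        a = rng.normal(size=(400, 2)) * 0.3
        b = np.array([6.0, 6.0]) + rng.normal(size=(40, 2)) * 0.3
        pts = np.vstack([a, b])
        before = localization_score(pts)
        best, curve = select_n_grid(pts, [8, 12, 16], seed=1)
        plan = grid_flatten(pts, best, seed=1)
        after = localization_score(pts[plan.indices])
        assert after < before

    def test_sparse_candidates_excluded_with_warning(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.5]])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                select_n_grid(pts, [2], seed=0, min_survivors=10)
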