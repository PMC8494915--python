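"""Feature extraction: distances, grids, RMSF/RMSD, contacts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from dioscope.md_features import (
    ContactTable,
    build_feature_matrix,
    compute_rmsd,
    compute_rmsf,
    count_contacts,
    pair_distance_series,
    select_differential_region_pairs,
    sidechain_center,
    time_grid,
)

from conftest import make_frames


class TestTimeGrid:
    def test_production_window_has_1900_steps(self):
        grid = time_grid(50.5, 1000.0, 0.5)
        assert len(grid) == 1900
        assert grid[0] == 50.5 and grid[-1] == 1000.0

    @pytest.mark.parametrize(
        "args,expected",
        [((0, 1, 0.5), [0.0, 0.5, 1.0]), ((0, 0, 0.5), [0.0])],
    )
    def test_small_grids(self, args, expected):
        assert time_grid(*args).tolist() == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            time_grid(0, 1, 0)
        with pytest.raises(ValueError):
            time_grid(1, 0, 0.5)


class TestSidechainCenter:
    def _residue(self, rows):
        return pd.DataFrame(rows, columns=["name", "element", "mass"])

    def test_equal_masses_midpoint(self):
        atoms = self._residue([("CB", "C", 12.0), ("CG", "C", 12.0)])
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        assert sidechain_center(atoms, coords) == pytest.approx([1.0, 0.0, 0.0])

    def test_mass_weighting(self):
        atoms = self._residue([("CB", "C", 12.011), ("OG", "O", 15.999)])
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        x = 15.999 / (12.011 + 15.999)
        assert sidechain_center(atoms, coords)[0] == pytest.approx(x, abs=1e-4)
        assert sidechain_center(atoms, coords)[0] == pytest.approx(0.5712, abs=1e-4)

    def test_glycine_falls_back_to_ca(self):
        atoms = self._residue(
            [("N", "N", 14.0), ("CA", "C", 12.0), ("C", "C", 12.0), ("O", "O", 16.0)]
        )
        coords = np.array([[0, 0, 0], [1.0, 2.0, 3.0], [2, 0, 0], [3, 0, 0]], dtype=float)
        assert sidechain_center(atoms, coords) == pytest.approx([1.0, 2.0, 3.0])

    def test_backbone_and_hydrogens_excluded(self):
        atoms = self._residue(
            [("CA", "C", 12.0), ("CB", "C", 12.0), ("HB1", "H", 1.0)]
        )
        coords = np.array([[9, 9, 9], [1, 1, 1], [5, 5, 5]], dtype=float)
        assert sidechain_center(atoms, coords) == pytest.approx([1.0, 1.0, 1.0])

    def test_empty_residue_errors(self):
        with pytest.raises(ValueError):
            sidechain_center(self._residue([]), np.empty((0, 3)))


class TestPairDistances:
    def test_static_pair_distance(self, two_residue_frames):
        series = pair_distance_series(two_residue_frames, (1, 2), (0.0, 2.0, 1.0))
        assert series == pytest.approx([5.0, 5.0, 5.0])

    def test_self_pair_rejected(self, two_residue_frames):
        with pytest.raises(ValueError):
            pair_distance_series(two_residue_frames, (2, 2), (0.0, 2.0, 1.0))

    def test_axis_displacement(self):
        frames = make_frames(
            [[[0, 0, 0], [3, 0, 0]], [[0, 0, 0], [4, 0, 0]]], resids=[1, 2]
        )
        series = pair_distance_series(frames, (1, 2), (0.0, 1.0, 1.0))
        assert series == pytest.approx([3.0, 4.0])

    def test_window_beyond_span_errors(self, two_residue_frames):
        with pytest.raises(ValueError):
            pair_distance_series(two_residue_frames, (1, 2), (0.0, 10.0, 1.0))

    def test_rigid_body_invariance(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(4, 6, 3))
        frames = make_frames(base, resids=[1, 2, 3, 4, 5, 6])
        ref = build_feature_matrix(frames).values
        moved = np.stack(
            [f @ Rotation.random(random_state=i).as_matrix().T + i for i, f in enumerate(base)]
        )
        out = build_feature_matrix(make_frames(moved, resids=[1, 2, 3, 4, 5, 6])).values
        np.testing.assert_allclose(out, ref, atol=1e-9)


class TestFeatureMatrix:
    def test_two_residues_one_row(self, two_residue_frames):
        fm = build_feature_matrix(two_residue_frames)
        assert fm.n_pairs == 1 and fm.pairs == [(1, 2)]

    @given(n=st.integers(min_value=2, max_value=24))
    @settings(max_examples=12, deadline=None)
    def test_all_pairs_count_identity(self, n):
        frames = make_frames(
            np.random.default_rng(n).normal(size=(2, n, 3)) * 0.1
            + np.arange(n)[None, :, None] * 5.0,
            resids=list(range(1, n + 1)),
        )
        fm = build_feature_matrix(frames)
        assert fm.n_pairs == n * (n - 1) // 2
        assert fm.pairs == sorted(fm.pairs)
        assert np.all(fm.values >= 0)

    def test_single_residue_rejected(self):
        frames = make_frames(np.zeros((2, 1, 3)), resids=[1])
        with pytest.raises(ValueError):
            build_feature_matrix(frames)


class TestRMSF:
    def test_static_structure_zero(self):
        frames = make_frames(np.tile(np.arange(9.0).reshape(1, 3, 3), (5, 1, 1)), names=["CA"] * 3, resids=[1, 2, 3])
        assert compute_rmsf(frames).rmsf.values == pytest.approx([0.0, 0.0, 0.0])

    def test_alternating_atom_without_superposition(self):
        coords = np.tile(np.arange(9.0).reshape(1, 3, 3), (4, 1, 1))
        coords[::2, 0, 0] += 0.3
        coords[1::2, 0, 0] -= 0.3
        frames = make_frames(coords, names=["CA"] * 3, resids=[1, 2, 3])
        rmsf = compute_rmsf(frames, superpose=False).rmsf.values
        assert rmsf == pytest.approx([0.3, 0.0, 0.0])

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(20, 4, 3)).cumsum(axis=0)
        frames = make_frames(coords, names=["CA"] * 4, resids=[1, 2, 3, 4])
        got = compute_rmsf(frames, superpose=False).rmsf.values
        mean = coords.mean(axis=0)
        expected = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_frame_permutation_invariance(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(10, 3, 3))
        frames = make_frames(coords, names=["CA"] * 3, resids=[1, 2, 3])
        shuffled = make_frames(coords[rng.permutation(10)], names=["CA"] * 3, resids=[1, 2, 3])
        np.testing.assert_allclose(
            compute_rmsf(frames).rmsf.values, compute_rmsf(shuffled).rmsf.values, atol=1e-9
        )


class TestRMSD:
    def test_reference_against_itself_is_zero(self, two_residue_frames):
        frames = make_frames(
            np.random.default_rng(0).normal(size=(1, 5, 3)), names=["CA"] * 5, resids=list(range(1, 6))
        )
        assert compute_rmsd(frames)[0] == pytest.approx(0.0, abs=1e-10)

    def test_rigid_translation_vanishes_after_superposition(self):
        base = np.random.default_rng(1).normal(size=(5, 3))
        coords = np.stack([base, base + np.array([3.0, -2.0, 1.0])])
        frames = make_frames(coords, names=["CA"] * 5, resids=list(range(1, 6)))
        rmsd = compute_rmsd(frames)
        assert rmsd[1] == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_atom_without_superposition(self):
        base = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        moved = base.copy()
        moved[0, 0] += 1.0
        frames = make_frames(np.stack([base, moved]), names=["CA"] * 2, resids=[1, 2])
        rmsd = compute_rmsd(frames, superpose=False)
        assert rmsd[1] == pytest.approx(np.sqrt(0.5))


def _brute_force_contacts(frames, cutoff, min_seq_sep=2):
    """Exhaustive per-frame atom-pair enumeration oracle."""
    atoms = frames.atoms
    events = {}
    resids = sorted(atoms["resid"].unique())
    for t in range(frames.n_frames):
        for ai, i in enumerate(resids):
            for j in resids[ai + 1 :]:
                if abs(i - j) < min_seq_sep:
                    continue
                pi = frames.coords[t][(atoms["resid"] == i).values]
                pj = frames.coords[t][(atoms["resid"] == j).values]
                dmin = np.min(np.linalg.norm(pi[:, None, :] - pj[None, :, :], axis=2))
                if dmin < cutoff:
                    events[(i, j)] = events.get((i, j), 0) + 1
    return events


class TestContacts:
    def _toy(self, gap):
        # residues 1, 3 separated by `gap` along x; residue 2 far away
        coords = [
            [[0, 0, 0], [0, 50, 0], [gap, 0, 0]],
            [[0, 0, 0], [0, 50, 0], [gap + 10, 0, 0]],
        ]
        return make_frames(coords, resids=[1, 2, 3])

    def test_exact_cutoff_is_not_a_contact(self):
        table = count_contacts(self._toy(4.0), cutoff=4.0, mode="unique_pairs")
        assert table.total == 0

    def test_just_below_cutoff_is_a_contact(self):
        table = count_contacts(self._toy(3.9), cutoff=4.0, mode="unique_pairs")
        assert table.total == 1
        assert table.lookup(1, 3) == 1

    def test_modes_agree_with_brute_force(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 12, size=(3, 12, 3))
        frames = make_frames(coords, resids=[1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 6, 6])
        oracle = _brute_force_contacts(frames, cutoff=5.0)
        got_pf = count_contacts(frames, cutoff=5.0, mode="pair_frames")
        got_up = count_contacts(frames, cutoff=5.0, mode="unique_pairs")
        assert got_pf.total == sum(oracle.values())
        assert got_up.total == len(oracle)
        for pair, n in oracle.items():
            assert got_pf.lookup(*pair) == n

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 10, size=(2, 8, 3))
        frames = make_frames(coords, resids=[1, 2, 3, 4, 5, 6, 7, 8])
        totals = [
            count_contacts(frames, cutoff=c, mode="pair_frames").total
            for c in (2.0, 4.0, 6.0, 8.0)
        ]
        assert totals == sorted(totals)


class TestDifferentialRegionPairs:
    def _tables(self, counts):
        out = {}
        for run, c in counts.items():
            df = pd.DataFrame([("A", "B", c)], columns=["label_a", "label_b", "count"])
            out[run] = ContactTable(counts=df, cutoff=4.0, mode="pair_frames", total=c)
        return out

    def test_apo_rich_pair_selected(self):
        tables = self._tables({"apo1": 150, "apo2": 140, "holo1": 5, "holo2": 8})
        assert select_differential_region_pairs(tables) == [("A", "B")]

    def test_ratio_violation_rejected(self):
        tables = self._tables({"apo1": 150, "apo2": 140, "holo1": 20, "holo2": 8})
        assert select_differential_region_pairs(tables) == []

    def test_equal_counts_rejected(self):
        tables = self._tables({"apo1": 150, "apo2": 150, "holo1": 150, "holo2": 150})
        assert select_differential_region_pairs(tables) == []

    def test_missing_run_errors(self):
        tables = self._tables({"apo1": 1, "apo2": 1, "holo1": 1})
        with pytest.raises(ValueError):
            select_differential_region_pairs(tables)
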