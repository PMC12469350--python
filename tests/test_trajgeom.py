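"""Trajectory geometry: dihedrals, Rg, COM distances, H-bonds, state switching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acpdyn.synthdata import gen_trajectory
from acpdyn.trajgeom import (FrameSeries, chi1, com_distance, dihedral,
                             hbond_occupancy, radius_of_gyration, read_frames_table,
                             switch_detect)


def oracle_dihedral(p1, p2, p3, p4):
    """Independent normal-vector atan2 formulation.

    Signed angle between the planes (p1,p2,p3) and (p2,p3,p4) around the
    central bond: atan2([n1 x n2] . u, n1 . n2) with u the central-bond unit
    vector, which is +180 for anti and 0 for eclipsed arrangements.
    """
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    u = b2 / np.linalg.norm(b2)
    return np.degrees(np.arctan2(np.dot(np.cross(n1, n2), u), np.dot(n1, n2)))


def random_rigid(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.normal(scale=20.0, size=3)


class TestDihedral:
    def test_trans_is_180(self):
        pts = [np.array(p, float) for p in
               [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)]]
        assert dihedral(*pts) == pytest.approx(180.0)

    def test_cis_is_zero(self):
        pts = [np.array(p, float) for p in
               [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)]]
        assert dihedral(*pts) == pytest.approx(0.0, abs=1e-12)

    def test_matches_oracle_on_seeded_random_cases(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            pts = rng.normal(scale=3.0, size=(4, 3))
            try:
                ours = dihedral(*pts)
            except ValueError:
                continue
            theirs = oracle_dihedral(*pts)
            if np.isclose(theirs, -180.0):
                theirs = 180.0
            assert ours == pytest.approx(theirs, abs=1e-10)

    def test_reversal_preserves_magnitude(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            pts = rng.normal(size=(4, 3))
            try:
                fwd = dihedral(*pts)
            except ValueError:
                continue
            rev = dihedral(*pts[::-1])
            assert abs(abs(fwd) - abs(rev)) < 1e-10

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestRgAndCOM:
    def test_single_atom_zero(self):
        assert radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_unit_masses_two_angstrom_apart(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(coords) == pytest.approx(1.0)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(scale=8.0, size=(40, 3))
        masses = rng.uniform(1.0, 16.0, size=40)
        rg0 = radius_of_gyration(coords, masses)
        for _ in range(100):
            rot, trans = random_rigid(rng)
            rg = radius_of_gyration(coords @ rot.T + trans, masses)
            assert abs(rg - rg0) < 1e-10

    def test_com_distance_degenerate_cases(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [1.0, 5.0, 0]])
        # selection containing only the target atom
        assert com_distance(coords, [2], coords[2]) == 0.0
        # two atoms symmetric about the target point
        assert com_distance(coords, [0, 1], np.array([1.0, 0, 0])) == pytest.approx(0.0)

    def test_com_matches_bruteforce_average(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(20, 3))
        masses = rng.uniform(1, 12, 20)
        sel = np.arange(12)
        com = np.array([np.sum(masses[sel] * coords[sel, k]) / masses[sel].sum()
                        for k in range(3)])
        b = rng.normal(size=3)
        assert com_distance(coords, sel, b, masses[sel]) == \
            pytest.approx(np.linalg.norm(com - b), abs=1e-12)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            com_distance(np.zeros((3, 3)), [], np.zeros(3))


class TestHBond:
    def _series_from_distances(self, dists):
        coords = np.zeros((len(dists), 2, 3))
        coords[:, 1, 0] = dists
        return FrameSeries(np.arange(len(dists), dtype=float),
                           [(19, "NE2"), (8, "O")], coords)

    def test_hand_counted_occupancy(self):
        s = self._series_from_distances([3.0, 3.6, 3.4, 4.0])
        assert hbond_occupancy(s, (19, "NE2"), (8, "O"), cutoff=3.5) == 0.5

    def test_boundary_and_monotonicity_in_cutoff(self):
        s = self._series_from_distances([3.0, 3.5, 3.6, 4.0, 2.0])
        occs = [hbond_occupancy(s, (19, "NE2"), (8, "O"), cutoff=c)
                for c in (0.0, 2.5, 3.5, 5.0)]
        assert occs[0] == 0.0 and occs[-1] == 1.0
        assert all(a <= b for a, b in zip(occs, occs[1:]))

    @given(st.lists(st.floats(0.5, 6.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_occupancy_counts_frames(self, dists):
        s = self._series_from_distances(dists)
        occ = hbond_occupancy(s, (19, "NE2"), (8, "O"))
        assert occ == sum(d <= 3.5 for d in dists) / len(dists)


class TestSwitchDetect:
    def test_alternating_series(self):
        angles = np.array([-70.0, -180.0] * 10)
        labels, trans = switch_detect(angles, [-70.0, -180.0], 30.0)
        assert trans == len(angles) - 1
        assert set(labels) == {0, 1}

    def test_wraparound_same_state(self):
        labels, trans = switch_detect(np.array([-179.0, 179.0]), [-180.0], 30.0)
        assert labels.tolist() == [0, 0] and trans == 0

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            switch_detect(np.zeros(3), [-70.0, -100.0], 30.0)

    def test_unassigned_frames_skipped_in_transitions(self):
        angles = np.array([-70.0, 0.0, -70.0, -180.0])
        labels, trans = switch_detect(angles, [-70.0, -180.0], 20.0)
        assert labels[1] == -1
        assert trans == 1


class TestGeneratedTrajectory:
    def test_truths_recovered(self):
        traj, truth = gen_trajectory(12, n_frames=2000)
        occ = hbond_occupancy(traj, (19, "NE2"), (8, "O"))
        assert occ == truth.truths["hbond_occupancy"]

        angles = np.array([chi1(traj, f, 42, "L")
                           for f in range(traj.coords.shape[0])])
        labels, trans = switch_detect(angles, truth.truths["chi1_states"], 30.0)
        assert trans == truth.truths["chi1_transitions"]
        for k, occ_true in enumerate(truth.truths["chi1_occupancies"]):
            assert float(np.mean(labels == k)) == pytest.approx(occ_true, abs=1e-12)

    def test_telegraph_occupancy_within_two_percent_at_1e4_frames(self):
        traj, truth = gen_trajectory(13, n_frames=10_000, chi1_dwell=(0.3, 0.7))
        angles = np.array([chi1(traj, f, 42, "L")
                           for f in range(traj.coords.shape[0])])
        labels, _ = switch_detect(angles, truth.truths["chi1_states"], 30.0)
        for k, occ_true in enumerate(truth.truths["chi1_occupancies"]):
            assert float(np.mean(labels == k)) == pytest.approx(occ_true, abs=0.02)

    def test_table_round_trip(self, tmp_path):
        traj, _ = gen_trajectory(3, n_frames=5)
        rows = []
        for f in range(traj.coords.shape[0]):
            for (res, name), xyz in zip(traj.atoms, traj.coords[f]):
                rows.append(f"{f} {res} {name} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}")
        p = tmp_path / "traj.txt"
        p.write_text("\n".join(rows))
        back = read_frames_table(p)
        assert back.atoms == traj.atoms
        np.testing.assert_allclose(back.coords, traj.coords, atol=1e-9)
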