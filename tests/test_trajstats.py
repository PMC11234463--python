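"""Trajectory windowing, RMSD/RMSF, CoM distances and contact counts."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from linkerlens import synthdata, trajstats
from linkerlens.structio import ELEMENT_MASSES
from linkerlens.trajstats import (
    Trajectory,
    com_distance,
    contact_count,
    kabsch_rmsd,
    read_trajectory_pdb,
    rmsf,
    selection_stats,
    window_last,
)


def uniform_traj(n_frames, dt, n_atoms=4):
    frames = np.zeros((n_frames, n_atoms, 3))
    return Trajectory(frames=frames, times=dt * np.arange(n_frames))


class TestWindowLast:
    @pytest.mark.parametrize(
        "n_frames, dt, duration, expected",
        [(1001, 1.0, 100.0, 101), (10001, 0.1, 100.0, 1001), (201, 1.0, 200.0, 201)],
    )
    def test_frame_accounting(self, n_frames, dt, duration, expected):
        win = window_last(uniform_traj(n_frames, dt), duration)
        assert win.n_frames == expected

    def test_pooling_three_trajectories(self):
        # three 1 µs runs sampled every 1 ns: last-100 ns windows pool to 303
        pools = [window_last(uniform_traj(1001, 1.0), 100.0).n_frames for _ in range(3)]
        assert sum(pools) == 303
        fine = [window_last(uniform_traj(10001, 0.1), 100.0).n_frames for _ in range(3)]
        assert sum(fine) == 3003

    def test_window_endpoints_inclusive(self):
        win = window_last(uniform_traj(11, 1.0), 5.0)
        assert win.times[0] == 5.0 and win.times[-1] == 10.0

    def test_bad_durations(self):
        with pytest.raises(ValueError):
            window_last(uniform_traj(11, 1.0), 0.0)
        with pytest.raises(ValueError):
            window_last(uniform_traj(11, 1.0), 50.0)


class TestKabschRmsd:
    def test_identical_sets_are_zero(self, rng):
        x = rng.normal(size=(10, 3))
        assert kabsch_rmsd(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_without_superposition(self, rng):
        x = rng.normal(size=(10, 3))
        assert kabsch_rmsd(x, x + [1.0, 0, 0], superpose=False) == pytest.approx(1.0)

    def test_rigid_rotation_superposes_to_zero(self, rng):
        x = rng.normal(size=(20, 3))
        rot = Rotation.from_euler("xyz", [30, -60, 110], degrees=True)
        assert kabsch_rmsd(x, rot.apply(x) + 5.0) < 1e-6

    def test_agrees_with_scipy_alignment_oracle(self, rng):
        """Optimal superposition RMSD equals scipy's align_vectors RSSD/√N."""
        x = rng.normal(size=(15, 3))
        y = x + rng.normal(scale=0.4, size=(15, 3))
        xc, yc = x - x.mean(0), y - y.mean(0)
        _, rssd = Rotation.align_vectors(xc, yc)
        assert kabsch_rmsd(x, y) == pytest.approx(rssd / np.sqrt(15), rel=1e-6)

    def test_too_few_atoms_with_superposition(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((2, 3)), np.ones((2, 3)), superpose=True)


class TestRmsf:
    def test_static_trajectory_is_all_zero(self):
        ref = synthdata.build_helix(10)
        traj = synthdata.gen_trajectory(ref, 0.0, 50, seed=1)
        prof = rmsf(traj)
        np.testing.assert_allclose(prof.per_atom, 0.0, atol=1e-12)

    def test_gaussian_jitter_matches_sqrt3_sigma(self):
        # i.i.d. N(0, σ²) per coordinate → per-atom RMSF → √3·σ
        ref = synthdata.build_helix(30)
        traj = synthdata.gen_trajectory(ref, 0.5, 5000, seed=7)
        prof = rmsf(traj, superpose=False)
        np.testing.assert_allclose(prof.per_atom, np.sqrt(3) * 0.5, rtol=0.03)

    def test_per_residue_is_mean_of_member_atoms(self):
        ref = synthdata.build_helix(6)
        traj = synthdata.gen_trajectory(ref, 0.4, 400, seed=8)
        prof = rmsf(traj, superpose=False,
                    residue_atom_indices=[np.array([0, 1]), np.array([2])])
        assert prof.per_residue[0] == pytest.approx(prof.per_atom[:2].mean())
        assert prof.per_residue[1] == pytest.approx(prof.per_atom[2])

    def test_superposition_removes_global_tumbling(self, rng):
        ref = synthdata.build_helix(20)
        base = ref.coords()
        frames = [base]
        for k in range(1, 200):
            rot = Rotation.from_euler("z", 2 * k, degrees=True)
            frames.append(rot.apply(base))
        traj = Trajectory(frames=np.stack(frames), times=np.arange(200, dtype=float))
        fitted = rmsf(traj, superpose=True)
        raw = rmsf(traj, superpose=False)
        assert fitted.per_atom.mean() < 0.01 * raw.per_atom.mean()

    def test_single_frame_is_an_error(self):
        ref = synthdata.build_helix(10)
        with pytest.raises(ValueError):
            rmsf(Trajectory(frames=ref.coords()[None], times=np.array([0.0])))


class TestComDistance:
    def test_single_atoms_345_triangle(self):
        frame = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        d = com_distance(frame, [0], [1], mass_weighted=False)
        assert d == pytest.approx(5.0)

    def test_equal_mass_pair_centroid(self):
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0], [10.0, 0, 0]])
        d = com_distance(frame, [0, 1], [2], mass_weighted=False)
        assert d == pytest.approx(9.0)

    def test_mass_weighted_carbon_oxygen_pair(self):
        # C at origin, O at (2,0,0): CoM x = 2·15.999/(12.011+15.999) = 1.1424
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0], [10.0, 0, 0]])
        masses = np.array([ELEMENT_MASSES["C"], ELEMENT_MASSES["O"], 1.0])
        d = com_distance(frame, [0, 1], [2], masses=masses, mass_weighted=True)
        expected = 10.0 - 2.0 * 15.999 / (12.011 + 15.999)
        assert d == pytest.approx(expected, abs=1e-4)
        assert d == pytest.approx(8.8576, abs=1e-4)

    def test_empty_selection_raises(self):
        with pytest.raises(ValueError):
            com_distance(np.zeros((3, 3)), [], [0], mass_weighted=False)


class TestContactCount:
    def test_strict_cutoff_boundary(self):
        frame = np.array([[0.0, 0, 0], [4.9, 0, 0], [5.1, 0, 0]])
        assert contact_count(frame, [0], [1, 2], cutoff=5.0) == 1

    def test_atoms_counted_not_pairs(self):
        # two source atoms both within 5 Å of one target atom → count is 1
        frame = np.array([[0.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0]])
        assert contact_count(frame, [0, 1], [2], cutoff=5.0) == 1

    def test_overlapping_selections_raise(self):
        with pytest.raises(ValueError, match="overlap"):
            contact_count(np.zeros((4, 3)), [0, 1], [1, 2])

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            n_src = rng.integers(1, 25)
            n_tgt = rng.integers(1, 26)
            frame = rng.uniform(0, 12, size=(n_src + n_tgt, 3))
            src = np.arange(n_src)
            tgt = np.arange(n_src, n_src + n_tgt)
            brute = sum(
                1
                for t in tgt
                if any(np.linalg.norm(frame[t] - frame[s]) < 5.0 for s in src)
            )
            assert contact_count(frame, src, tgt) == brute

    def test_monotone_in_cutoff(self, rng):
        frame = rng.uniform(0, 15, size=(40, 3))
        src, tgt = np.arange(15), np.arange(15, 40)
        counts = [contact_count(frame, src, tgt, cutoff=c) for c in (2, 4, 6, 8, 12)]
        assert counts == sorted(counts)


class TestSelectionStatsAndIO:
    def test_trajectory_roundtrip_through_multimodel_pdb(self):
        ref = synthdata.build_helix(8)
        traj = synthdata.gen_trajectory(ref, 0.3, 5, dt_ns=2.0, seed=3)
        from linkerlens.structio import write_pdb

        models = []
        for frame in traj.frames:
            s = synthdata.build_helix(8)
            for i, atom in enumerate(s.atoms()):
                atom.coords = frame[i]
            models.append(s)
        text = write_pdb(models, times_ns=traj.times)
        back = read_trajectory_pdb(text)
        np.testing.assert_allclose(back.frames, traj.frames, atol=5e-4)
        np.testing.assert_allclose(back.times, traj.times)

    def test_per_frame_stats_lengths_agree(self):
        ref = synthdata.build_helix(12)
        traj = synthdata.gen_trajectory(ref, 0.2, 20, seed=4)
        stats = selection_stats(
            traj, np.arange(4), np.arange(6, 12), masses=np.ones(12)
        )
        assert len(stats.com_distances) == len(stats.contact_counts) == 20
        assert np.all(stats.contact_counts >= 0)
        assert np.all(stats.contact_counts <= 6)
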