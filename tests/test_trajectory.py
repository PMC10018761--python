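"""Trajectory containers, I/O round trips, and periodic unwrapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sdpdiff as s
from sdpdiff.trajectory import (
    Box,
    Trajectory,
    TrajectoryError,
    read_gro_xtc,
    read_internal_csv,
    read_trajectory,
    read_xyz,
    write_gro_xtc,
    write_internal_csv,
    write_xyz,
)


def small_traj(n_mol=3, n_frames=8, box=5.0, seed=11, species=True):
    rng = np.random.default_rng(seed)
    pos = rng.random((n_mol, n_frames, 3)) * box
    return Trajectory(
        times=np.arange(n_frames) * 0.25,
        positions=pos,
        box=np.full((n_frames, 3), box),
        species=np.array(["water"] * n_mol, dtype=object) if species else None,
    )


class TestContainers:
    def test_box_validation(self):
        with pytest.raises(TrajectoryError):
            Box(np.array([1.0, -1.0, 1.0]))
        with pytest.raises(TrajectoryError):
            Box.from_lengths_angles([5, 5, 5], [90, 90, 60])
        assert Box.cubic(5.0).min_length == 5.0

    def test_times_must_be_uniform_and_increasing(self):
        pos = np.zeros((1, 3, 3))
        with pytest.raises(TrajectoryError):
            Trajectory(times=[0.0, 0.1, 0.05], positions=pos, box=[5, 5, 5])
        with pytest.raises(TrajectoryError):
            Trajectory(times=[0.0, 0.1, 0.35], positions=pos, box=[5, 5, 5])

    def test_species_selection(self):
        t = small_traj()
        t.species[0] = "polymer"
        water = t.select_species("water")
        assert water.n_molecules == 2
        with pytest.raises(TrajectoryError):
            small_traj(species=False).select_species("water")


class TestInternalCsv:
    def test_round_trip_bit_exact(self, tmp_path):
        t = small_traj()
        path = tmp_path / "traj.csv"
        write_internal_csv(t, path)
        back = read_internal_csv(path)
        np.testing.assert_array_equal(back.times, t.times)
        np.testing.assert_array_equal(back.mol_ids, t.mol_ids)
        assert np.abs(back.positions - t.positions).max() <= 1e-9
        assert list(back.species) == list(t.species)

    def test_missing_frame_rejected(self, tmp_path):
        t = small_traj()
        path = tmp_path / "traj.csv"
        write_internal_csv(t, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(TrajectoryError, match="every molecule"):
            read_internal_csv(path)

    def test_dispatch_by_extension(self, tmp_path):
        t = small_traj()
        path = tmp_path / "traj.csv"
        write_internal_csv(t, path)
        back = read_trajectory(str(path))
        assert back.n_frames == t.n_frames
        with pytest.raises(FileNotFoundError):
            read_trajectory(str(tmp_path / "absent.csv"))


class TestXyz:
    def test_round_trip(self, tmp_path):
        t = small_traj()
        path = tmp_path / "traj.xyz"
        write_xyz(t, path)
        back = read_xyz(path)
        np.testing.assert_allclose(back.positions, t.positions, atol=1e-12)
        np.testing.assert_allclose(back.times, t.times)
        np.testing.assert_allclose(back.box, t.box)

    def test_missing_box_is_an_error(self, tmp_path):
        path = tmp_path / "nobox.xyz"
        path.write_text("1\nframe 0\nO 1.0 2.0 3.0\n")
        with pytest.raises(TrajectoryError, match="box required"):
            read_xyz(path)


class TestGroXtc:
    def test_round_trip_within_xtc_quantization(self, tmp_path):
        t = small_traj(n_mol=5, n_frames=20)
        gro, xtc = str(tmp_path / "top.gro"), str(tmp_path / "traj.xtc")
        write_gro_xtc(t, gro, xtc)
        back = read_gro_xtc(gro, xtc)
        assert back.n_molecules == 5 and back.n_frames == 20
        # XTC stores coordinates with 1e-3 Angstrom quantization
        assert np.abs(back.positions - t.positions).max() <= 1e-3
        assert set(back.species) == {"water"}
        np.testing.assert_allclose(back.times, t.times, atol=1e-6)


class TestUnwrap:
    def test_single_axis_boundary_crossing(self):
        pos = np.array([[[4.9, 1.0, 1.0], [0.1, 1.0, 1.0]]])
        t = Trajectory(times=[0.0, 0.1], positions=pos, box=[5.0, 5.0, 5.0])
        u = s.unwrap(t)
        np.testing.assert_allclose(u.positions[0, 1], [5.1, 1.0, 1.0])

    def test_stationary_is_identity(self):
        pos = np.ones((2, 5, 3))
        t = Trajectory(times=np.arange(5) * 0.1, positions=pos, box=[5.0] * 3)
        np.testing.assert_array_equal(s.unwrap(t).positions, pos)

    def test_recovers_ground_truth_random_walk(self, rng):
        truth = np.cumsum(rng.normal(scale=0.4, size=(4, 200, 3)), axis=1) + 2.5
        t = Trajectory(
            times=np.arange(200) * 0.01, positions=truth, box=[5.0] * 3
        )
        wrapped = s.wrap(t)
        u = s.unwrap(wrapped)
        # unwrapping reconstructs continuity up to a global image offset per molecule
        offset = u.positions[:, :1] - truth[:, :1]
        np.testing.assert_allclose(u.positions, truth + offset, atol=1e-9)

    def test_half_box_displacement_is_ambiguous(self):
        pos = np.array([[[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]]])
        t = Trajectory(times=[0.0, 0.1], positions=pos, box=[5.0] * 3)
        with pytest.raises(TrajectoryError, match="molecule 0 between frames 0 and 1"):
            s.unwrap(t)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_wrap_unwrap_identities(self, seed):
        rng = np.random.default_rng(seed)
        walk = np.cumsum(rng.normal(scale=0.3, size=(2, 40, 3)), axis=1)
        t = Trajectory(times=np.arange(40) * 0.1, positions=walk, box=[4.0] * 3)
        w = s.wrap(t)
        u = s.unwrap(w)
        # wrap(unwrap(wrapped)) reproduces the wrapped input up to round-off;
        # coordinates within epsilon of the boundary may legally flip between
        # 0 and L, so compare with the periodic distance
        diff = np.abs(s.wrap(u).positions - w.positions)
        periodic = np.minimum(diff, 4.0 - diff)
        assert periodic.max() <= 1e-12
        # unwrap is idempotent (up to float reconstruction round-off)
        np.testing.assert_allclose(s.unwrap(u).positions, u.positions, atol=1e-12)
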