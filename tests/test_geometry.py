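import numpy as np
import pytest
from _oracles import make_atomistic_helix
from scipy.spatial.transform import Rotation

from tmdimer.geometry import (
    DEFAULT_LENGTH_BINS,
    LengthDistribution,
    crossing_angle,
    density_projection,
    dimer_geometry,
    distribution_difference,
    fit_helix_axis,
    helix_lengths,
    length_distribution,
    tilt_angle,
)
from tmdimer.structures import Frame, Trajectory, build_ideal_cg_helix, coarse_grain
from tmdimer.synthetic import InterfaceState, place_dimer


class TestHelixAxis:
    def test_collinear_beads_give_line_direction(self):
        line = np.column_stack([np.zeros(10), np.zeros(10), 0.15 * np.arange(10)])
        axis, _ = fit_helix_axis(line)
        assert np.allclose(axis, [0, 0, 1], atol=1e-12)

    def test_ideal_helix_axis_is_construction_axis(self, ideal_helix):
        axis, _ = fit_helix_axis(ideal_helix.bb_positions("A"))
        assert np.allclose(axis, [0, 0, 1], atol=1e-9)

    def test_axis_equivariance_under_rotation(self, ideal_helix):
        rot = Rotation.from_euler("zyx", [33.0, 71.0, -15.0], degrees=True).as_matrix()
        rotated = ideal_helix.transformed(rot, np.zeros(3))
        axis, _ = fit_helix_axis(rotated.bb_positions("A"))
        assert np.allclose(axis, rot @ np.array([0, 0, 1.0]), atol=1e-6)

    def test_too_few_beads_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_helix_axis(np.zeros((2, 3)))


class TestTiltAngle:
    @pytest.mark.parametrize(
        "axis,expected", [((0, 0, 1), 0.0), ((1, 0, 0), 90.0), ((0, 0, -1), 0.0)]
    )
    def test_reference_directions(self, axis, expected):
        assert tilt_angle(axis) == pytest.approx(expected, abs=1e-12)

    def test_known_inclination_recovered(self):
        theta = np.deg2rad(25.0)
        axis = np.array([np.sin(theta), 0.0, np.cos(theta)])
        assert tilt_angle(axis) == pytest.approx(25.0, abs=1e-9)
        assert tilt_angle(axis, signed=True) == pytest.approx(25.0, abs=1e-9)
        assert tilt_angle(-axis, signed=True) == pytest.approx(-25.0, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="non-zero"):
            tilt_angle(np.zeros(3))


class TestCrossingAngle:
    def test_parallel_axes_flagged_and_zero(self, ideal_helix):
        frame = place_dimer(ideal_helix, ideal_helix, InterfaceState("s", 0, 180, 0, 0.9))
        geo = dimer_geometry(frame)
        assert geo.crossing_angle == 0.0 and geo.parallel

    def test_construction_oracle(self, ideal_helix):
        frame = place_dimer(
            ideal_helix, ideal_helix, InterfaceState("s", -120, 60, -32.05, 0.9)
        )
        assert crossing_angle(frame) == pytest.approx(-32.05, abs=1e-6)

    def test_invariant_under_rigid_body_motion(self, state_frames):
        frame = state_frames["nmr-like"]
        angle = crossing_angle(frame)
        rot = Rotation.from_euler("xyz", [17.0, -58.0, 96.0], degrees=True).as_matrix()
        moved = Frame(frame.structure.transformed(rot, np.array([3.0, -1.0, 2.0])))
        assert crossing_angle(moved) == pytest.approx(angle, abs=1e-6)

    def test_mirror_reflection_flips_the_sign(self, state_frames):
        frame = state_frames["nmr-like"]
        angle = crossing_angle(frame)
        mirrored_positions = frame.structure.positions * np.array([1.0, 1.0, -1.0])
        mirrored = Frame(frame.structure.with_positions(mirrored_positions))
        assert crossing_angle(mirrored) == pytest.approx(-angle, abs=1e-6)
        assert angle < 0  # the NMR-like interface is right-handed


class TestHelixLength:
    def test_straight_line_length_is_rise_times_offset(self):
        line = build_ideal_cg_helix(25, bead_radius=0.0)
        lengths = helix_lengths(line, i_offset=12, chain="A")
        assert np.allclose(lengths, 1.80, atol=1e-12)
        assert len(lengths) == 13  # 25 - 12 valid start residues

    def test_ideal_helix_matches_chord_geometry(self, ideal_helix):
        expected = np.sqrt((12 * 0.15) ** 2 + (2 * 0.23 * np.sin(np.deg2rad(60))) ** 2)
        lengths = helix_lengths(ideal_helix, chain="A")
        assert np.allclose(lengths, expected, atol=1e-12)

    def test_noiseless_trajectory_has_zero_variance(self, state_frames):
        frames = [
            Frame(state_frames["parallel-sym"].structure, time=float(t))
            for t in range(3)
        ]
        traj = Trajectory(frames, 1.0)
        from tmdimer.geometry import helix_length_series

        per_frame, dist = helix_length_series(traj)
        assert np.std(np.concatenate(per_frame)) < 1e-12
        assert np.count_nonzero(dist.probabilities) == 1

    def test_short_helix_rejected(self):
        short = build_ideal_cg_helix(10)
        with pytest.raises(ValueError, match="i_offset"):
            helix_lengths(short, i_offset=12)

    def test_ca_and_com_mappings_give_different_distributions(self):
        atoms = make_atomistic_helix(25)
        lengths_ca = helix_lengths(coarse_grain(atoms, "CA"), chain="A")
        lengths_com = helix_lengths(coarse_grain(atoms, "COM"), chain="A")
        assert not np.allclose(lengths_ca, lengths_com)


class TestDistributionDifference:
    def test_identical_distributions_score_zero(self):
        p = length_distribution(np.full(50, 1.8))
        assert distribution_difference(p, p) == 0.0

    def test_disjoint_supports_reach_the_maximum(self):
        p = length_distribution(np.full(50, 1.5))
        q = length_distribution(np.full(50, 2.2))
        assert distribution_difference(p, q) == pytest.approx(2.0)

    def test_hand_computed_l1(self):
        edges = np.array([0.0, 1.0, 2.0, 3.0])
        p = LengthDistribution(edges, np.array([0.5, 0.3, 0.2]))
        q = LengthDistribution(edges, np.array([0.2, 0.3, 0.5]))
        assert distribution_difference(p, q) == pytest.approx(0.6)
        assert distribution_difference(p, q, scale=10.0) == pytest.approx(6.0)

    def test_binning_mismatch_rejected(self):
        p = LengthDistribution(np.array([0.0, 1.0, 2.0]), np.array([0.5, 0.5]))
        q = LengthDistribution(np.array([0.0, 0.5, 2.0]), np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="binning"):
            distribution_difference(p, q)


class TestDensityProjection:
    def test_single_frame_mass_equals_bead_count(self, state_frames):
        frame = state_frames["parallel-sym"]
        hist, _, _ = density_projection([frame])
        assert hist.sum() == len(frame.structure.chain("B").positions)

    def test_rotated_copies_project_identically(self, state_frames):
        frame = state_frames["nmr-like"]
        rot = Rotation.from_euler("z", 73.0, degrees=True).as_matrix()
        rotated = Frame(frame.structure.transformed(rot, np.array([0.5, 0.2, -0.1])))
        hist_single, _, _ = density_projection([frame])
        hist_both, _, _ = density_projection([frame, rotated])
        assert np.array_equal(hist_both, 2 * hist_single)

    def test_two_state_data_is_bimodal(self, state_frames):
        frames = [state_frames["parallel-sym"], state_frames["parallel-rot"]]
        # rotate the second interface to the opposite side of helix A
        rot = Rotation.from_euler("z", 180.0, degrees=True).as_matrix()
        frames[1] = Frame(frames[1].structure.transformed(rot, np.zeros(3)))
        hist, xe, _ = density_projection(frames, bins=8, extent=1.6)
        occupancy_x = hist.sum(axis=1)
        # mass on both sides of helix A
        assert occupancy_x[: 3].sum() > 0 and occupancy_x[-3:].sum() > 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no frames"):
            density_projection([])
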