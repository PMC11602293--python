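"""Superposition, RMSF/ΔRMSF, and the auxiliary trajectory summaries."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from mscscreen import (
    TrajectoryEnsemble,
    compute_rmsf,
    count_hydrogen_bonds,
    delta_rmsf,
    kabsch_superpose,
    radius_of_gyration,
    shrake_rupley_sasa,
    summarize_trajectory,
)
from mscscreen.flexibility import RMSFProfile
from mscscreen.errors import (
    DegenerateSuperpositionError,
    InsufficientFramesError,
    ResidueAlignmentError,
)


def brute_force_min_rmsd(mobile, reference, n_restarts=40):
    """Independent oracle: minimize RMSD over rotations by multi-start
    optimization of a rotation vector after centering both frames."""
    mobile = mobile - mobile.mean(axis=0)
    reference = reference - reference.mean(axis=0)

    def rmsd_of(rotvec):
        rotated = Rotation.from_rotvec(rotvec).apply(mobile)
        return np.sqrt(np.mean(np.sum((rotated - reference) ** 2, axis=1)))

    rng = np.random.default_rng(0)
    best = np.inf
    for _ in range(n_restarts):
        start = rng.uniform(-np.pi, np.pi, size=3)
        result = minimize(rmsd_of, start, method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, result.fun)
    return best


class TestKabsch:
    def test_identical_frames_zero_rmsd(self):
        frame = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        aligned, rmsd = kabsch_superpose(frame, frame)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(aligned, frame, atol=1e-10)

    def test_rigid_rotation_recovered(self):
        frame = np.array([[0.0, 0, 0], [2, 0, 0], [0, 3, 0], [1, 1, 1]])
        rotated = Rotation.from_euler("z", 90, degrees=True).apply(frame)
        _, rmsd = kabsch_superpose(rotated, frame)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_oracle(self):
        reference = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        mobile = reference.copy()
        mobile[3] += [1.0, 0.0, 0.0]  # one atom displaced 1 Å
        _, rmsd = kabsch_superpose(mobile, reference)
        assert rmsd == pytest.approx(brute_force_min_rmsd(mobile, reference), abs=1e-6)

    @pytest.mark.parametrize("frame", [
        np.array([[0.0, 0, 0], [1, 0, 0]]),  # too few atoms
        np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]]),  # collinear
    ])
    def test_degenerate_inputs_rejected(self, frame):
        with pytest.raises(DegenerateSuperpositionError):
            kabsch_superpose(frame, frame + 1.0)


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        frames = np.tile(np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0]]), (10, 1, 1))
        profile = compute_rmsf(TrajectoryEnsemble(frames=frames), superpose=False)
        np.testing.assert_allclose(profile.rmsf_values, 0.0, atol=1e-12)

    def test_alternating_single_atom_hand_value(self):
        # atom hops between (0,0,0) and (2,0,0): mean (1,0,0), deviation 1 Å
        frames = np.array([[[0.0, 0, 0]], [[2, 0, 0]]] * 4)
        profile = compute_rmsf(TrajectoryEnsemble(frames=frames),
                               equilibration_fraction=0.0, superpose=False)
        assert profile.rmsf_values[0] == pytest.approx(1.0)

    def test_gaussian_jitter_matches_closed_form(self):
        rng = np.random.default_rng(42)
        sigma = 0.5
        base = rng.uniform(-5, 5, size=(30, 3))
        frames = base[None] + rng.normal(scale=sigma, size=(2000, 30, 3))
        profile = compute_rmsf(TrajectoryEnsemble(frames=frames),
                               equilibration_fraction=0.0, superpose=False)
        expected = sigma * np.sqrt(3.0)
        assert np.all(np.abs(profile.rmsf_values / expected - 1.0) < 0.05)

    def test_equilibration_discard_can_exhaust_frames(self):
        frames = np.zeros((3, 4, 3))
        with pytest.raises(InsufficientFramesError):
            compute_rmsf(TrajectoryEnsemble(frames=frames), equilibration_fraction=0.9)

    def test_invariant_under_global_rigid_motion(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(-5, 5, size=(12, 3))
        frames = base[None] + rng.normal(scale=0.3, size=(40, 12, 3))
        motion = Rotation.from_euler("xyz", [20, -40, 65], degrees=True)
        moved = np.array([motion.apply(f) + np.array([5.0, -2.0, 1.0]) for f in frames])
        ref = compute_rmsf(TrajectoryEnsemble(frames=frames),
                           equilibration_fraction=0.0, superpose=True)
        rot = compute_rmsf(TrajectoryEnsemble(frames=moved),
                           equilibration_fraction=0.0, superpose=True)
        np.testing.assert_allclose(rot.rmsf_values, ref.rmsf_values, atol=1e-8)


class TestDeltaRmsf:
    @pytest.mark.parametrize("residue,high,low,expected", [
        (67, 1.368, 0.526, 0.842),
        (61, 1.215, 1.325, -0.110),
    ])
    def test_printed_values(self, residue, high, low, expected):
        comparison = delta_rmsf(
            RMSFProfile([residue], np.array([high]), temperature=328.0),
            RMSFProfile([residue], np.array([low]), temperature=298.0),
        )
        assert comparison.delta_rmsf[0] == pytest.approx(expected, abs=1e-12)

    def test_self_difference_zero_and_antisymmetry(self):
        rng = np.random.default_rng(1)
        ids = [5, 9, 30]
        a = RMSFProfile(ids, rng.uniform(0.1, 2.0, 3))
        b = RMSFProfile(ids, rng.uniform(0.1, 2.0, 3))
        np.testing.assert_allclose(delta_rmsf(a, a).delta_rmsf, 0.0)
        np.testing.assert_allclose(delta_rmsf(a, b).delta_rmsf,
                                   -delta_rmsf(b, a).delta_rmsf)

    def test_id_mismatch_lists_difference(self):
        a = RMSFProfile([1, 2, 3], np.ones(3))
        b = RMSFProfile([1, 2, 4], np.ones(3))
        with pytest.raises(ResidueAlignmentError, match=r"\[3, 4\]"):
            delta_rmsf(a, b)


class TestRadiusOfGyration:
    def test_single_atom(self):
        assert radius_of_gyration([[1.0, 2.0, 3.0]]) == 0.0

    def test_two_unit_masses(self):
        assert radius_of_gyration([[0.0, 0, 0], [2.0, 0, 0]]) == pytest.approx(1.0)

    def test_square_corners(self):
        square = [[0.0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0]]
        assert radius_of_gyration(square) == pytest.approx(np.sqrt(2.0))


class TestHydrogenBonds:
    def test_empty_lists(self):
        assert count_hydrogen_bonds([[0, 0, 0]], []) == 0

    def test_geometry_criterion(self):
        donor = [[0.0, 0, 0]]
        hydrogen = [[1.0, 0, 0]]
        acceptor_good = [[3.0, 0, 0]]  # D-A 3.0 Å, D-H...A angle 180°
        assert count_hydrogen_bonds(donor, acceptor_good, hydrogen) == 1
        assert count_hydrogen_bonds(donor, [[3.6, 0, 0]], hydrogen) == 0

    def test_angle_rejection(self):
        donor = [[0.0, 0, 0]]
        hydrogen = [[0.0, 1.0, 0]]  # puts acceptor at ~45° from the D-H axis
        acceptor = [[2.0, 0.0, 0]]
        assert count_hydrogen_bonds(donor, acceptor, hydrogen, angle_cutoff=120) == 0
        assert count_hydrogen_bonds(donor, acceptor) == 1  # heavy-atom mode


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        area = shrake_rupley_sasa([[0.0, 0, 0]], [1.9], probe_radius=1.4,
                                  n_sphere_points=960)
        exact = 4.0 * np.pi * 3.3**2
        assert area == pytest.approx(exact, rel=0.02)

    def test_caged_atom_buried(self):
        cage = [[3.0, 0, 0], [-3, 0, 0], [0, 3, 0], [0, -3, 0], [0, 0, 3], [0, 0, -3]]
        coords = [[0.0, 0, 0]] + cage
        radii = [1.5] + [3.0] * 6
        per_atom = shrake_rupley_sasa(coords, radii, per_atom=True)
        assert per_atom[0] == pytest.approx(0.0, abs=1e-9)

    def test_point_count_convergence(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(-3, 3, size=(10, 3))
        radii = np.full(10, 1.7)
        coarse = shrake_rupley_sasa(coords, radii, n_sphere_points=480)
        fine = shrake_rupley_sasa(coords, radii, n_sphere_points=960)
        assert abs(fine / coarse - 1.0) < 0.01


def test_summary_series_shapes_and_zero_rmsd_reference():
    rng = np.random.default_rng(2)
    frames = rng.uniform(-4, 4, size=(5, 6, 3))
    summary = summarize_trajectory(TrajectoryEnsemble(frames=frames))
    assert summary.rmsd_series.shape == (5,)
    assert summary.rg_series.shape == (5,)
    assert summary.rmsd_series[0] == pytest.approx(0.0, abs=1e-9)
    assert np.all(summary.rg_series >= 0)
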