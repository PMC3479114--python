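"""Superposition, RMSD/RMSF, B-factor conversion and smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pullkit.geometry import (
    Series,
    apply_transform,
    bfactor_to_rmsf,
    kabsch_superpose,
    rmsd_series,
    rmsf_profile,
    rmsf_to_bfactor,
    running_average,
)
from pullkit.structure import Selection, Trajectory

from conftest import static_trajectory


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def grid_search_rmsd(mobile, reference, coarse=24, refinements=4):
    """Brute-force minimum RMSD over a dense rotation grid (Euler zyz),
    with local grid refinement around the best cell."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def rmsd_of(r):
        return np.sqrt(((mob @ r.T - ref) ** 2).sum(axis=1).mean())

    def euler_zyz(a, b, c):
        return rotation_matrix([0, 0, 1], a) @ rotation_matrix([0, 1, 0], b) @ rotation_matrix([0, 0, 1], c)

    best = (np.inf, (0.0, 0.0, 0.0))
    widths = (2 * np.pi, np.pi, 2 * np.pi)
    centers = (np.pi, np.pi / 2, np.pi)
    for _ in range(refinements + 1):
        axes = [np.linspace(c - w / 2, c + w / 2, coarse) for c, w in zip(centers, widths)]
        for a in axes[0]:
            for b in axes[1]:
                for c in axes[2]:
                    v = rmsd_of(euler_zyz(a, b, c))
                    if v < best[0]:
                        best = (v, (a, b, c))
        centers = best[1]
        widths = tuple(2.5 * w / coarse for w in widths)
    return best[0]


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)

    def test_recovers_rigid_motion(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        r_true = rotation_matrix([0, 0, 1], np.pi / 2)
        moved = pts @ r_true.T + np.array([1.0, -2.0, 3.0])
        rot, trans, rmsd = kabsch_superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(rot @ r_true, np.eye(3), atol=1e-9)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        ref = rng.normal(size=(10, 3))
        mobile = ref + 0.5 * rng.normal(size=(10, 3))
        mobile = mobile @ rotation_matrix([1, 2, 3], 1.1).T + 5.0
        _, _, rmsd = kabsch_superpose(mobile, ref)
        oracle = grid_search_rmsd(mobile, ref)
        assert rmsd <= oracle + 1e-9  # Kabsch is the true optimum
        assert abs(rmsd - oracle) < 1e-3

    def test_proper_rotation_under_reflection_ambiguity(self):
        # near-planar points invite improper solutions; determinant must stay +1
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(6, 3)) * np.array([1.0, 1.0, 0.01])
        mobile = -ref  # a reflection of the reference
        rot, _, _ = kabsch_superpose(mobile, ref)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000), st.floats(0.1, 3.0))
    def test_rigid_motion_invariance(self, seed, angle):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(7, 3))
        b = a + 0.3 * rng.normal(size=(7, 3))
        _, _, rmsd0 = kabsch_superpose(a, b)
        moved = a @ rotation_matrix(rng.normal(size=3) + 0.1, angle).T + rng.normal(size=3)
        _, _, rmsd1 = kabsch_superpose(moved, b)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)


class TestRmsdSeries:
    def test_static_trajectory_is_zero(self, tiny_structure):
        traj = static_trajectory(tiny_structure)
        series = rmsd_series(traj, tiny_structure, Selection(label="all"))
        np.testing.assert_allclose(series.values, 0.0, atol=1e-12)

    def test_rigid_motion_removed(self, tiny_structure):
        traj = static_trajectory(tiny_structure, n_frames=4)
        for f in range(4):
            r = rotation_matrix([0, 1, 0], 0.3 * f)
            traj.frames[f] = traj.frames[f] @ r.T + f * np.array([1.0, 2.0, 0.0])
        series = rmsd_series(traj, tiny_structure, Selection(label="all"))
        np.testing.assert_allclose(series.values, 0.0, atol=1e-9)

    def test_uniform_displacement_closed_form(self, tiny_structure):
        # fit on immobile CA atoms, measure SER atoms displaced by d along +x
        traj = static_trajectory(tiny_structure, n_frames=3)
        meas = Selection(label="ser", residue_names=["SER"])
        idx = meas.resolve(tiny_structure)
        d = 2.5
        traj.frames[2][idx] += np.array([d, 0.0, 0.0])
        fit = Selection(label="gly-ala", residue_names=["GLY", "ALA"])
        series = rmsd_series(traj, tiny_structure, fit, meas)
        assert series.values[1] == pytest.approx(0.0, abs=1e-9)
        assert series.values[2] == pytest.approx(d, abs=1e-6)


class TestRmsf:
    def test_static_is_zero(self, tiny_structure):
        traj = static_trajectory(tiny_structure, n_frames=4)
        prof = rmsf_profile(traj, Selection(label="all"))
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-12)

    def test_single_oscillating_atom_closed_form(self, tiny_structure):
        # one atom alternates +-a along x with equal dwell; others fixed
        traj = static_trajectory(tiny_structure, n_frames=8)
        a = 0.8
        for f in range(8):
            traj.frames[f][4, 0] += a if f % 2 == 0 else -a
        prof = rmsf_profile(traj, Selection(label="all"), n_passes=0)
        assert prof.rmsf[4] == pytest.approx(a, rel=1e-6)
        np.testing.assert_allclose(prof.rmsf[:4], 0.0, atol=1e-9)

    def test_window_selects_frames(self, tiny_structure):
        traj = static_trajectory(tiny_structure, n_frames=10)
        prof = rmsf_profile(traj, Selection(label="all"), window=(30.0, 70.0))
        assert prof.n_frames_used == 5
        assert prof.window == (30.0, 70.0)
        with pytest.raises(ValueError):
            rmsf_profile(traj, Selection(label="all"), window=(200.0, 300.0))

    def test_global_rigid_motion_invariance(self, tiny_structure):
        rng = np.random.default_rng(5)
        traj = static_trajectory(tiny_structure, n_frames=6)
        traj.frames += 0.2 * rng.normal(size=traj.frames.shape)
        prof0 = rmsf_profile(traj, Selection(label="all"))
        moved = traj.frames.copy()
        for f in range(6):
            moved[f] = moved[f] @ rotation_matrix([1, 1, 0], 0.5 * f).T + f * 3.0
        traj2 = Trajectory(moved, traj.times, tiny_structure)
        prof1 = rmsf_profile(traj2, Selection(label="all"))
        np.testing.assert_allclose(prof1.rmsf, prof0.rmsf, atol=1e-6)

    def test_shield_beads_fluctuate_more_than_core(self, toy_domain, equil_traj):
        _, _, spec = toy_domain
        prof = rmsf_profile(equil_traj, Selection(label="beads", atom_names=["CB"]),
                            window=(100.0, 500.0))
        core = np.isin(prof.residue_numbers, [i + 1 for i in spec.core_members])
        shield = np.isin(prof.residue_numbers, [i + 1 for i in spec.shield_members])
        assert prof.rmsf[shield].mean() > prof.rmsf[core].mean()


class TestBFactor:
    def test_analytic_values(self):
        assert bfactor_to_rmsf(0.0) == 0.0
        assert bfactor_to_rmsf(8.0 * np.pi**2 / 3.0) == pytest.approx(1.0, abs=1e-12)

    def test_round_trip_and_monotonicity(self):
        b = np.linspace(0.0, 80.0, 30)
        np.testing.assert_allclose(rmsf_to_bfactor(bfactor_to_rmsf(b)), b, atol=1e-12)
        assert np.all(np.diff(bfactor_to_rmsf(b)) > 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bfactor_to_rmsf(-1.0)


class TestRunningAverage:
    def test_constant_unchanged(self):
        s = Series(np.arange(10) * 10.0, np.full(10, 3.3))
        out = running_average(s, width=20.0)
        np.testing.assert_allclose(out.values, 3.3)

    def test_alternating_series_enumeration(self):
        # +-1 at 10 ps spacing, 20 ps window = 2 samples (centered-right):
        # every interior value pairs +1 with -1 -> 0; last sample is truncated
        values = np.array([1.0, -1.0] * 5)
        s = Series(np.arange(10) * 10.0, values)
        out = running_average(s, width=20.0)
        np.testing.assert_allclose(out.values[:-1], 0.0, atol=1e-12)
        assert out.values[-1] == values[-1]

    def test_noise_variance_reduction(self):
        rng = np.random.default_rng(123)
        n = 10_000
        s = Series(np.arange(n) * 10.0, rng.normal(size=n))
        w = 5
        out = running_average(s, width=w * 10.0)
        interior = out.values[w : n - w]
        assert interior.var() == pytest.approx(1.0 / w, rel=0.2)

    def test_width_below_spacing_rejected(self):
        s = Series(np.arange(5) * 10.0, np.zeros(5))
        with pytest.raises(ValueError):
            running_average(s, width=5.0)

    def test_length_preserved(self):
        s = Series(np.arange(17) * 10.0, np.sin(np.arange(17.0)))
        assert len(running_average(s, width=40.0)) == 17
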