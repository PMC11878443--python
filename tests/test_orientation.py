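"""Symmetry disambiguation, outlier rejection and axis-angle decomposition."""

import numpy as np
import pytest

from birtrack import (
    BirTrajectory,
    CrystalModel,
    OrientationSeries,
    SpotTable,
    clean_series,
    detect_quake,
    disambiguate,
    net_rotation,
    point_group_rotations,
    refine_orientation,
    reject_misindexed,
    relative_rotation,
    scramble_indexing,
    simulate_orientation_track,
)
from birtrack.diffraction import predict_reflections
from birtrack.orientation import read_orientation_table, write_orientation_table
from birtrack.rotations import axis_angle_matrix, random_rotation

from conftest import quaternion_oracle


class TestPointGroupRotations:
    def test_trivial_group(self):
        ops = point_group_rotations("1")
        assert len(ops) == 1
        np.testing.assert_array_equal(ops[0], np.eye(3, dtype=int))

    def test_222_has_four_ops_closed_under_multiplication(self):
        ops = point_group_rotations("222")
        assert len(ops) == 4
        keys = {tuple(S.ravel()) for S in ops}
        for A in ops:
            for B in ops:
                assert tuple((A @ B).ravel()) in keys

    def test_fourfold_about_c_present_in_pg4(self):
        ops = point_group_rotations("4")
        assert len(ops) == 4
        fourfold = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]])
        keys = {tuple(S.ravel()) for S in ops}
        assert tuple(fourfold.ravel()) in keys or tuple(fourfold.T.ravel()) in keys

    @pytest.mark.parametrize("symbol,n", [("2", 2), ("422", 8), ("23", 12), ("432", 24), ("P212121", 4)])
    def test_group_orders(self, symbol, n):
        assert len(point_group_rotations(symbol)) == n

    def test_unknown_symbol_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            point_group_rotations("frobnicate")

    def test_ops_preserve_cell_metric(self):
        cell = CrystalModel(cell=(10, 10, 14, 90, 90, 90), point_group="4")
        M = cell.cell_matrix()
        G = M.T @ M
        for S in point_group_rotations("4"):
            np.testing.assert_allclose(S.T @ G @ S, G, atol=1e-9)


class TestRelativeRotation:
    def test_identity_returns_convention_axis(self):
        M = np.diag([10.0, 12.0, 14.0])
        axis, angle = relative_rotation(M, M)
        assert angle == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_array_equal(axis, [0, 0, 1])

    def test_constructed_z_rotation(self):
        M = np.diag([10.0, 12.0, 14.0])
        Mi = axis_angle_matrix((0, 0, 1), 5.0) @ M
        axis, angle = relative_rotation(M, Mi)
        assert angle == pytest.approx(5.0, abs=1e-9)
        np.testing.assert_allclose(axis, [0, 0, 1], atol=1e-9)

    def test_agrees_with_quaternion_oracle_on_random_rotations(self):
        rng = np.random.default_rng(8)
        M = np.diag([10.0, 12.0, 14.0])
        for _ in range(300):
            R = random_rotation(rng)
            axis, angle = relative_rotation(M, R @ M)
            axis_o, angle_o = quaternion_oracle(R)
            if axis_o[np.flatnonzero(np.abs(axis_o) > 1e-12)[0]] < 0:
                axis_o = -axis_o
            assert angle == pytest.approx(angle_o, abs=1e-8)
            np.testing.assert_allclose(axis, axis_o, atol=1e-8)

    def test_inverse_pair_has_equal_angle_and_inverse_rotation(self):
        rng = np.random.default_rng(9)
        M = np.diag([10.0, 12.0, 14.0])
        Mi = random_rotation(rng) @ M
        ax_f, ang_f = relative_rotation(M, Mi)
        ax_b, ang_b = relative_rotation(Mi, M)
        assert ang_f == pytest.approx(ang_b, abs=1e-9)
        # forward and backward rotations compose to the identity
        Rf = axis_angle_matrix(ax_f, ang_f)
        Rb = axis_angle_matrix(ax_b, ang_b)
        assert np.allclose(Rf @ Rb, np.eye(3), atol=1e-9) or np.allclose(Rf @ Rb.T, np.eye(3), atol=1e-9)

    def test_procrustes_projects_noisy_input(self):
        rng = np.random.default_rng(10)
        M = np.diag([10.0, 12.0, 14.0])
        R = axis_angle_matrix((0, 1, 0), 2.0)
        noisy = R @ M + rng.normal(0, 1e-4, (3, 3))
        _, angle = relative_rotation(M, noisy)
        assert angle == pytest.approx(2.0, abs=1e-3)


class TestDisambiguate:
    def test_identity_ops_leave_series_unchanged(self, ortho_model, drift_traj):
        series = simulate_orientation_track(ortho_model, drift_traj)
        out = disambiguate(series, [np.eye(3, dtype=int)])
        np.testing.assert_array_equal(out.matrices, series.matrices)

    @pytest.mark.parametrize("pg,cell", [
        ("2", (10, 12, 14, 90, 100, 90)),
        ("222", (10, 12, 14, 90, 90, 90)),
        ("4", (10, 10, 14, 90, 90, 90)),
    ])
    def test_recovers_scrambled_track_modulo_global_op(self, pg, cell):
        model = CrystalModel(cell=cell, point_group=pg, seed=1)
        traj = BirTrajectory(n_frames=80, fluence_per_frame=0.01, drift_rate=1.0)
        series = simulate_orientation_track(model, traj)
        scrambled = scramble_indexing(series, model, noise_sd=0.0, seed=13)
        out = disambiguate(scrambled)
        ops = point_group_rotations(pg)
        residuals = [
            max(np.linalg.norm(out.matrices[i] - series.matrices[i] @ S) for i in range(series.n_frames))
            for S in ops
        ]
        assert min(residuals) < 1e-9

    def test_tie_broken_toward_lower_op_index(self):
        ops = [
            np.diag([-1, -1, 1]).astype(int),
            np.diag([1, -1, -1]).astype(int),
        ]
        series = OrientationSeries(
            matrices=np.stack([np.eye(3), np.eye(3)]),
            fluence_axis=np.array([0.01, 0.02]),
        )
        out = disambiguate(series, ops)
        # both candidates are Frobenius-equidistant from frame 0; lower index wins
        np.testing.assert_array_equal(out.matrices[1], np.diag([-1.0, -1.0, 1.0]))

    def test_idempotent_and_equivariant_under_global_op(self, ortho_model, drift_traj):
        series = simulate_orientation_track(ortho_model, drift_traj)
        scrambled = scramble_indexing(series, ortho_model, seed=17)
        once = disambiguate(scrambled)
        twice = disambiguate(once)
        np.testing.assert_allclose(once.matrices, twice.matrices, atol=1e-12)
        S = point_group_rotations("222")[2]
        pre = OrientationSeries(
            matrices=np.einsum("nij,jk->nik", scrambled.matrices, S),
            fluence_axis=scrambled.fluence_axis,
            point_group="222",
        )
        out_pre = disambiguate(pre)
        np.testing.assert_allclose(out_pre.matrices, np.einsum("nij,jk->nik", once.matrices, S), atol=1e-12)


class TestRejectMisindexed:
    def test_constant_series_nothing_flagged(self):
        series = OrientationSeries(
            matrices=np.tile(np.diag([10.0, 12.0, 14.0]), (20, 1, 1)),
            fluence_axis=np.arange(1, 21) * 0.01,
        )
        out = reject_misindexed(series)
        assert out.valid.all()

    def test_single_large_outlier_flagged_alone(self, ortho_model):
        """Population sigma comes from real drift; the outlier towers over it."""
        traj = BirTrajectory(n_frames=20, fluence_per_frame=0.01, drift_rate=2.0)
        series = simulate_orientation_track(ortho_model, traj)
        mats = series.matrices.copy()
        sigma = mats.reshape(20, 9).std(axis=0)
        mats[5] += (10 * sigma.max() + 1.0) * np.sign(np.random.default_rng(11).normal(size=(3, 3)))
        out = reject_misindexed(
            OrientationSeries(matrices=mats, fluence_axis=series.fluence_axis)
        )
        assert not out.valid[5]
        assert out.valid.sum() == 19

    def test_smooth_drift_not_flagged(self, ortho_model):
        traj = BirTrajectory(n_frames=100, fluence_per_frame=0.01, drift_rate=2.0)
        series = simulate_orientation_track(ortho_model, traj)
        out = reject_misindexed(series)
        assert out.valid.all()

    def test_short_series_is_noop_with_warning(self, caplog):
        series = OrientationSeries(
            matrices=np.tile(np.eye(3), (2, 1, 1)), fluence_axis=np.array([0.01, 0.02])
        )
        out = reject_misindexed(series)
        assert out.valid.all()


class TestNetRotation:
    def test_pure_drift_recovers_angle_and_axis(self, ortho_model, drift_traj):
        series = simulate_orientation_track(ortho_model, drift_traj)
        rot = net_rotation(series)
        assert 1.49 - 1e-9 <= rot.final_angle <= 1.50
        angle_to_axis = np.rad2deg(np.arccos(np.clip(np.dot(rot.final_axis, [0, 1, 0]), -1, 1)))
        assert angle_to_axis < 0.1

    def test_rotation_about_c_leaves_c_fixed(self):
        M0 = np.diag([10.0, 12.0, 14.0])  # c along lab z
        Mi = axis_angle_matrix((0, 0, 1), 4.0) @ M0
        series = OrientationSeries(matrices=np.stack([M0, Mi]), fluence_axis=np.array([0.01, 0.02]))
        rot = net_rotation(series)
        np.testing.assert_allclose(rot.per_vector_angles[-1], [4.0, 4.0, 0.0], atol=1e-9)

    def test_static_series_all_zero(self):
        series = OrientationSeries(
            matrices=np.tile(np.diag([10.0, 12.0, 14.0]), (5, 1, 1)),
            fluence_axis=np.arange(1, 6) * 0.1,
        )
        rot = net_rotation(series)
        np.testing.assert_allclose(rot.per_frame_angle, 0.0, atol=1e-12)
        np.testing.assert_allclose(rot.per_vector_angles, 0.0, atol=1e-9)

    def test_per_vector_angles_bounded_by_net_angle(self):
        rng = np.random.default_rng(12)
        M0 = np.diag([10.0, 12.0, 14.0])
        mats = [M0] + [random_rotation(rng) @ M0 for _ in range(30)]
        series = OrientationSeries(matrices=np.stack(mats), fluence_axis=np.arange(1, 32) * 0.01)
        rot = net_rotation(series)
        assert np.all(rot.per_vector_angles <= rot.per_frame_angle[:, None] + 1e-6)

    def test_max_fluence_selects_earlier_frame(self, ortho_model, drift_traj):
        series = simulate_orientation_track(ortho_model, drift_traj)
        rot = net_rotation(series, max_fluence=0.75)
        # frame 74 carries end-of-frame fluence 0.75 and was rotated by 0.74 deg
        assert rot.final_fluence == pytest.approx(0.75, abs=1e-12)
        assert rot.final_angle == pytest.approx(0.74, abs=1e-9)

    def test_single_valid_frame_rejected(self):
        series = OrientationSeries(
            matrices=np.tile(np.eye(3), (3, 1, 1)),
            fluence_axis=np.arange(1, 4) * 0.01,
            valid=np.array([True, False, False]),
        )
        with pytest.raises(ValueError, match="two valid frames"):
            net_rotation(series)


class TestDetectQuake:
    def test_drift_only_returns_none(self, ortho_model, drift_traj):
        rot = net_rotation(simulate_orientation_track(ortho_model, drift_traj))
        assert detect_quake(rot, threshold=1.0) is None

    def test_quake_found_within_one_frame_of_imposed_fluence(self, ortho_model):
        traj = BirTrajectory(
            n_frames=60, fluence_per_frame=0.01, drift_rate=0.0,
            quake_fluence=0.08, quake_angle=3.0,
        )
        rot = net_rotation(simulate_orientation_track(ortho_model, traj))
        q = detect_quake(rot, threshold=1.0)
        assert q is not None
        assert abs(q - 0.08) <= 0.01

    def test_short_series_returns_none(self):
        series = OrientationSeries(
            matrices=np.tile(np.eye(3), (2, 1, 1)), fluence_axis=np.array([0.01, 0.02])
        )
        assert detect_quake(net_rotation(series), threshold=0.1) is None


class TestCleanSeriesEndToEnd:
    def test_recovery_with_noise_and_misindexing(self, ortho_model, drift_traj):
        series = simulate_orientation_track(ortho_model, drift_traj)
        scrambled = scramble_indexing(series, ortho_model, noise_sd=1e-3, misindex_fraction=0.1, seed=3)
        rot = net_rotation(clean_series(scrambled))
        assert abs(rot.final_angle - 1.49) / 1.49 < 0.1
        axis_err = np.rad2deg(np.arccos(np.clip(abs(np.dot(rot.final_axis, [0, 1, 0])), -1, 1)))
        assert axis_err < 2.0

    def test_table_round_trip_preserves_series(self, ortho_model, drift_traj, tmp_path):
        series = simulate_orientation_track(ortho_model, drift_traj)
        write_orientation_table(series, tmp_path / "o.tsv")
        back = read_orientation_table(tmp_path / "o.tsv", point_group="222")
        np.testing.assert_allclose(back.matrices, series.matrices, rtol=1e-8)
        np.testing.assert_allclose(back.fluence_axis, series.fluence_axis, rtol=1e-8)


class TestRefineOrientation:
    def _spots_for(self, model, M, det):
        pred = predict_reflections(M, det, model.resolution_limit, model.rocking_halfwidth)
        bright = model.base_intensity(pred["hkl"]) * pred["rocking"] > 500
        return SpotTable(centers=np.rint(pred["position"][bright]).astype(int), mask_radius=10)

    def test_fixed_point_at_truth(self, det_wide):
        model = CrystalModel(cell=(10, 12, 14, 90, 90, 90), resolution_limit=1.2, seed=5)
        M = axis_angle_matrix((1, 0, 0), 0.1) @ model.cell_matrix()
        spots = self._spots_for(model, M, det_wide)
        res = refine_orientation(spots, M, model.cell, det_wide, model.rocking_halfwidth, model.resolution_limit)
        assert res.success
        _, dtheta = relative_rotation(M, res.matrix)
        assert dtheta < 0.02  # limited by 1-px center rounding

    def test_half_degree_offset_recovered(self, det_wide):
        model = CrystalModel(cell=(10, 12, 14, 90, 90, 90), resolution_limit=1.2, seed=5)
        M = model.cell_matrix()
        spots = SpotTable(
            centers=predict_reflections(M, det_wide, 1.2, model.rocking_halfwidth)["position"],
            mask_radius=10,
        )
        candidate = axis_angle_matrix((0, 0, 1), 0.5) @ M
        res = refine_orientation(spots, candidate, model.cell, det_wide, model.rocking_halfwidth, 1.2)
        assert res.success
        _, dtheta = relative_rotation(M, res.matrix)
        assert dtheta < 0.01

    def test_far_off_candidate_refused(self, det_wide):
        model = CrystalModel(cell=(10, 12, 14, 90, 90, 90), resolution_limit=1.2, seed=5)
        M = model.cell_matrix()
        spots = self._spots_for(model, M, det_wide)
        candidate = axis_angle_matrix((1, 1, 0) / np.sqrt(2), 30.0) @ M
        res = refine_orientation(spots, candidate, model.cell, det_wide, model.rocking_halfwidth, 1.2)
        if res.success:
            # if it "converged", it must not have actually recovered the truth
            _, dtheta = relative_rotation(M, res.matrix)
            assert dtheta > 1.0
        else:
            np.testing.assert_array_equal(res.matrix, candidate)
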