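import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import whiskscape as ws
from whiskscape.contact_sim import (CLASS_NONE, CLASS_RESTING, CLASS_WHISKING,
                                    HeadPose, first_contact, plane_in_head_frame,
                                    wall_frame)
from whiskscape.kinematics import sweep_whisker


def brute_force_first_contact(sweep, normal, offset):
    """Exhaustive double loop over steps and nodes (oracle)."""
    for s in range(sweep.steps):
        for n in range(sweep.nodes_by_step.shape[1]):
            if float(sweep.nodes_by_step[s, n] @ normal) >= offset:
                return s, n
    return None


class TestPlaneFrame:
    def test_unrotated_pose(self):
        n, off = plane_in_head_frame(HeadPose(10.0, 0.0, 0.0))
        assert np.allclose(n, [0, 1, 0])
        assert off == 10.0

    def test_pitch_up_90_is_ground_plane(self):
        # head pitched fully up: the wall plays the role of the ground
        n, _ = plane_in_head_frame(HeadPose(5.0, 0.0, 90.0))
        assert np.allclose(n, [0, 0, -1], atol=1e-12)

    def test_yaw_minus_90_faces_right_whiskers(self):
        n, _ = plane_in_head_frame(HeadPose(5.0, -90.0, 0.0))
        assert np.allclose(n, [1, 0, 0], atol=1e-12)

    def test_normal_is_unit_everywhere(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pose = HeadPose(5.0, rng.uniform(-90, 90), rng.uniform(-90, 90))
            for order in ("yaw_then_pitch", "pitch_then_yaw"):
                n, _ = plane_in_head_frame(pose, order)
                assert np.linalg.norm(n) == pytest.approx(1.0)

    def test_orders_agree_on_single_axis_slices(self):
        for yaw, pitch in ((25.0, 0.0), (0.0, -60.0), (-85.0, 0.0)):
            n1, _ = plane_in_head_frame(HeadPose(5, yaw, pitch), "yaw_then_pitch")
            n2, _ = plane_in_head_frame(HeadPose(5, yaw, pitch), "pitch_then_yaw")
            assert np.allclose(n1, n2, atol=1e-12)

    def test_wall_frame_orthonormal(self):
        n, lat, vert = wall_frame(HeadPose(5.0, 37.0, -52.0))
        m = np.stack([n, lat, vert])
        assert np.allclose(m @ m.T, np.eye(3), atol=1e-12)


class TestFirstContact:
    def test_unreachable_plane(self, default_array, coeffs, schedule):
        sw = sweep_whisker(default_array.get("R-C2"), coeffs, schedule)
        rec = first_contact(sw, np.array([0.0, 1.0, 0.0]), 1e4)
        assert rec.contact_class == CLASS_NONE
        assert rec.contact_step == -1 and rec.contact_node == -1
        assert np.isnan(rec.theta_impact)

    def test_resting_contact_at_step_zero(self, default_array, coeffs, schedule):
        sw = sweep_whisker(default_array.get("R-C2"), coeffs, schedule)
        rec = first_contact(sw, np.array([0.0, 1.0, 0.0]), -1e4)
        assert rec.contact_class == CLASS_RESTING
        assert rec.contact_step == 0
        assert rec.theta_impact == pytest.approx(sw.theta_by_step[0])

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(label=st.sampled_from(["R-B3", "L-delta", "R-C6", "L-A1"]),
           yaw=st.floats(-90, 90), pitch=st.floats(-90, 90),
           dist=st.floats(0, 40))
    def test_matches_bruteforce_oracle(self, label, yaw, pitch, dist):
        array = ws.build_default_array()
        sw = sweep_whisker(array.get(label), ws.KinematicCoeffs.default(),
                           ws.ProtractionSchedule(step_size=1.0))  # coarse: keeps the loop cheap
        normal, offset = plane_in_head_frame(HeadPose(dist, yaw, pitch))
        rec = first_contact(sw, normal, offset)
        oracle = brute_force_first_contact(sw, normal, offset)
        if oracle is None:
            assert rec.contact_class == CLASS_NONE
        else:
            assert (rec.contact_step, rec.contact_node) == oracle

    def test_whisking_theta_within_protraction_range(self, default_array, coeffs, schedule):
        w = default_array.get("R-C2")
        sw = sweep_whisker(w, coeffs, schedule)
        normal, offset = plane_in_head_frame(HeadPose(10.0, 0.0, 0.0))
        rec = first_contact(sw, normal, offset)
        assert rec.contact_class == CLASS_WHISKING
        assert w.theta_rest < rec.theta_impact <= w.theta_rest + 60.0


class TestSimulateGrid:
    def test_equivalent_to_first_contact_on_random_probes(self, small_table,
                                                          default_array, coeffs, schedule):
        sweeps = ws.sweep_all(default_array, coeffs, schedule)
        rng = np.random.default_rng(11)
        t = small_table
        for _ in range(120):
            w = rng.integers(t.n_whiskers)
            d = rng.integers(len(t.distances))
            iy = rng.integers(len(t.yaws))
            ip = rng.integers(len(t.pitches))
            pose = HeadPose(float(t.distances[d]), float(t.yaws[iy]), float(t.pitches[ip]))
            normal, offset = plane_in_head_frame(pose)
            rec = first_contact(sweeps[w], normal, offset, pose)
            assert rec.contact_class == t.contact_class[w, d, iy, ip]
            assert rec.contact_step == t.contact_step[w, d, iy, ip]
            assert rec.contact_node == t.contact_node[w, d, iy, ip]

    def test_distance_zero_always_reachable(self, small_table):
        any_contact = (small_table.contact_class != CLASS_NONE).any(axis=0)
        assert any_contact[0].all()  # nose touching the wall

    def test_left_right_reflection_symmetry_exact(self, small_table):
        t = small_table
        L, R = t.side_mask("left"), t.side_mask("right")
        assert np.array_equal(t.contact_class[L][:, :, ::-1, :], t.contact_class[R])
        thL = np.nan_to_num(t.theta_impact[L][:, :, ::-1, :], nan=-1.0)
        thR = np.nan_to_num(t.theta_impact[R], nan=-1.0)
        assert np.array_equal(thL, thR)
        assert np.array_equal(t.contact_node[L][:, :, ::-1, :], t.contact_node[R])

    def test_class_step_consistency(self, small_table):
        t = small_table
        assert np.all((t.contact_class == CLASS_RESTING) == (t.contact_step == 0))
        assert np.all((t.contact_class == CLASS_WHISKING) == (t.contact_step > 0))
        assert np.all((t.contact_class == CLASS_NONE) == (t.contact_step == -1))

    def test_theta_impact_monotone_in_distance(self, small_table):
        t = small_table
        th = t.theta_impact.astype(float).copy()
        th[t.contact_class != CLASS_WHISKING] = np.nan
        diffs = np.diff(th, axis=1)
        assert not np.any(diffs < -1e-6)

    def test_ragged_schedule_path(self, default_array, coeffs, small_grid):
        # full-retraction sweeps have per-whisker step counts; the per-whisker
        # fallback must agree with first_contact as well
        sch = ws.ProtractionSchedule(start_mode="full_retraction")
        sub = ws.ArraySpec(tuple(default_array.side("right")[:4]))
        table = ws.simulate_grid(sub, coeffs, sch, small_grid)
        sweeps = ws.sweep_all(sub, coeffs, sch)
        assert len({s.steps for s in sweeps}) > 1
        rng = np.random.default_rng(5)
        for _ in range(40):
            w = rng.integers(4)
            d = rng.integers(len(small_grid.distances))
            iy = rng.integers(len(small_grid.yaws))
            ip = rng.integers(len(small_grid.pitches))
            pose = HeadPose(float(small_grid.distances[d]),
                            float(small_grid.yaws[iy]), float(small_grid.pitches[ip]))
            normal, offset = plane_in_head_frame(pose)
            rec = first_contact(sweeps[w], normal, offset, pose)
            assert rec.contact_step == table.contact_step[w, d, iy, ip]

    def test_resting_fraction_rises_toward_wallward_yaw(self, small_table):
        t = small_table
        iy90, iy0 = t.yaw_index(90.0), t.yaw_index(0.0)
        for row in "ABCDE":
            m = t.side_mask("left") & (t.rows == row)
            f90 = (t.contact_class[m][:, :, iy90, :] == CLASS_RESTING).mean()
            f0 = (t.contact_class[m][:, :, iy0, :] == CLASS_RESTING).mean()
            assert f90 > f0

    def test_hdf5_roundtrip(self, small_table, tmp_path):
        path = tmp_path / "table.h5"
        small_table.to_hdf5(path)
        back = ws.ContactTable.from_hdf5(path)
        assert back.labels == small_table.labels
        assert np.array_equal(back.contact_class, small_table.contact_class)
        assert np.array_equal(np.nan_to_num(back.theta_impact),
                              np.nan_to_num(small_table.theta_impact))

    def test_long_form_dataframe(self, small_table):
        df = small_table.to_dataframe()
        assert len(df) == small_table.n_whiskers * small_table.contact_class[0].size
        assert set(df.contact_class.cat.categories) == {"none", "resting", "whisking"}


class TestCylinder:
    def test_plane_limit(self, default_array, coeffs, schedule):
        poses = [HeadPose(10.0, 0.0, 0.0)]
        sub = ws.ArraySpec(tuple(default_array.side("right")))
        df = ws.cylinder_contact_check(sub, coeffs, schedule, 1e6, poses)
        assert len(df) > 0
        assert df.dtheta_deg.max() < 0.01

    def test_noncontacting_whiskers_excluded(self, default_array, coeffs, schedule):
        poses = [HeadPose(10.0, 0.0, 0.0)]
        df = ws.cylinder_contact_check(default_array, coeffs, schedule, 140.0, poses)
        assert len(df) > 0
        assert "R-C6" not in set(df.label)  # a 3 mm whisker cannot reach 10 mm

    def test_invalid_radius(self, default_array, coeffs, schedule):
        from whiskscape.array_model import ParameterError
        with pytest.raises(ParameterError):
            ws.cylinder_contact_check(default_array, coeffs, schedule, -1.0, [])
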