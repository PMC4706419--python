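import numpy as np
import pandas as pd
import pytest

import whiskscape as ws
from whiskscape.array_model import ParameterError
from whiskscape.contact_sim import CLASS_NONE, CLASS_RESTING, CLASS_WHISKING, ContactTable
from whiskscape.inference import (correlation_fixed_pose, correlation_vs_uncertainty,
                                  group_average_maps, uniqueness,
                                  uniqueness_bruteforce)


def synthetic_table(rng, n_whiskers=8, n_poses=120, theta_linear=False):
    """Random (or exactly linear) contact table on a degenerate 1-D pose axis.

    Synthetic stand-in: class/angle fields are drawn at random, not produced
    by the kinematic simulation; used to exercise the statistics in isolation.
    """
    cls = rng.integers(0, 3, size=(n_whiskers, n_poses)).astype(np.int8)
    theta = np.full((n_whiskers, n_poses), np.nan, dtype=np.float32)
    dists = np.arange(n_poses, dtype=float)
    for w in range(n_whiskers):
        whisk = cls[w] == CLASS_WHISKING
        if theta_linear:
            theta[w, whisk] = 2.0 * dists[whisk] + 30.0 + w
        else:
            theta[w, whisk] = np.round(rng.uniform(60, 170, whisk.sum()), 1)
        theta[w, cls[w] == CLASS_RESTING] = 70.0 + w
    step = np.where(cls == CLASS_WHISKING, 5, np.where(cls == CLASS_RESTING, 0, -1))
    rows = np.array(list("ABCDE") * 2)[:n_whiskers]
    return ContactTable(
        labels=[f"W{i}" for i in range(n_whiskers)],
        rows=rows, cols=np.arange(n_whiskers) % 7,
        sides=np.array(["right", "left"] * (n_whiskers // 2)),
        distances=dists, yaws=np.array([0.0]), pitches=np.array([0.0]),
        contact_class=cls[:, :, None, None], theta_impact=theta[:, :, None, None],
        contact_step=step[:, :, None, None].astype(np.int32),
        contact_node=np.zeros_like(step)[:, :, None, None].astype(np.int16),
    )


class TestCorrelationFixedPose:
    def test_perfectly_linear_theta_gives_r_one(self):
        t = synthetic_table(np.random.default_rng(0), theta_linear=True)
        df = correlation_fixed_pose(t, 0.0, 0.0)
        ok = df[df.n_whisking >= 3]
        assert np.allclose(ok.r, 1.0)

    def test_degenerate_pool_is_nan_not_zero(self):
        rng = np.random.default_rng(1)
        t = synthetic_table(rng, n_poses=6)
        t.contact_class[0] = CLASS_NONE
        t.theta_impact[0] = np.nan
        df = correlation_fixed_pose(t, 0.0, 0.0).set_index("label")
        assert np.isnan(df.loc["W0", "r"])
        assert df.loc["W0", "n_whisking"] == 0

    def test_off_grid_pose_rejected(self, small_table):
        with pytest.raises(IndexError):
            correlation_fixed_pose(small_table, 12.5, 0.0)


class TestCorrelationVsUncertainty:
    def test_zero_uncertainty_consistent_with_fixed_pose(self, small_table):
        # row pool at u=0 uses exactly the yaw=0 whisking contacts
        curve = correlation_vs_uncertainty(small_table, "yaw", [0.0])
        iy = small_table.yaw_index(0.0)
        ip = small_table.pitch_index(0.0)
        m = small_table.side_mask("left") & (small_table.rows == "C")
        whisk = small_table.contact_class[m][:, :, iy, ip] == CLASS_WHISKING
        d = np.broadcast_to(small_table.distances, whisk.shape)[whisk]
        th = small_table.theta_impact[m][:, :, iy, ip][whisk].astype(float)
        from scipy.stats import pearsonr
        assert curve.r_by_row.loc[0.0, "C"] == pytest.approx(pearsonr(d, th)[0])

    def test_window_widening_changes_pool_size(self, small_table):
        curve = correlation_vs_uncertainty(small_table, "yaw", [0.0, 60.0, 180.0])
        n = curve.n_by_row["C"].to_numpy()
        assert n[0] < n[1] < n[2]

    def test_invalid_axis_and_range(self, small_table):
        with pytest.raises(ParameterError):
            correlation_vs_uncertainty(small_table, "roll", [0.0])
        with pytest.raises(ParameterError):
            correlation_vs_uncertainty(small_table, "yaw", [200.0])


class TestUniqueness:
    def test_single_pose_table_is_unique(self):
        t = synthetic_table(np.random.default_rng(2), n_poses=1)
        res = uniqueness(t, 5.0)
        assert res.n_considered == 1 and res.fraction_unique == 1.0

    @pytest.mark.parametrize("min_whisking", [0, 2])
    def test_matches_allpairs_oracle_on_random_subtables(self, min_whisking):
        for seed in range(4):
            t = synthetic_table(np.random.default_rng(seed), n_whiskers=6, n_poses=200)
            fast = uniqueness(t, 20.0, min_whisking)
            slow = uniqueness_bruteforce(t, 20.0, min_whisking)
            assert (fast.n_considered, fast.n_unique) == (slow.n_considered, slow.n_unique)

    def test_monotone_in_tolerance(self, small_table):
        f = [uniqueness(small_table, tol).fraction_unique for tol in (1.0, 5.0, 10.0)]
        assert f[0] >= f[1] >= f[2]

    def test_min_whisking_restricts_considered_set(self, small_table):
        r0 = uniqueness(small_table, 5.0, 0)
        r3 = uniqueness(small_table, 5.0, 3)
        assert r3.n_considered < r0.n_considered
        assert r3.fraction_unique >= r0.fraction_unique

    def test_strict_inequality_at_exact_tolerance(self):
        # two poses whose single whisking angle differs by exactly the
        # tolerance are distinguishable (strict < comparison)
        t = synthetic_table(np.random.default_rng(3), n_whiskers=2, n_poses=2)
        t.contact_class[:] = CLASS_WHISKING
        t.contact_step[:] = 5
        t.theta_impact[0, :, 0, 0] = [100.0, 105.0]
        t.theta_impact[1, :, 0, 0] = [100.0, 105.0]
        assert uniqueness(t, 5.0).n_unique == 2
        assert uniqueness(t, 5.01).n_unique == 0

    def test_binned_method_counts_distinct_bin_vectors(self):
        t = synthetic_table(np.random.default_rng(4), n_whiskers=2, n_poses=2)
        t.contact_class[:] = CLASS_WHISKING
        t.contact_step[:] = 5
        t.theta_impact[0, :, 0, 0] = [101.0, 104.0]   # same 5-deg bin
        t.theta_impact[1, :, 0, 0] = [101.0, 104.0]
        assert uniqueness(t, 5.0, method="binned").n_unique == 0
        t.theta_impact[0, :, 0, 0] = [104.0, 106.0]   # adjacent bins
        assert uniqueness(t, 5.0, method="binned").n_unique == 2

    def test_invalid_tolerance(self, small_table):
        with pytest.raises(ParameterError):
            uniqueness(small_table, 0.0)


class TestGroupAverageMaps:
    def test_singleton_group_mean_equals_member(self, small_table):
        gm = group_average_maps(small_table, "row")
        t = small_table
        iy = t.yaw_index(0.0)
        m = t.side_mask("left") & (t.rows == "B")
        cls = t.contact_class[m][:, :, iy, :]
        th = t.theta_impact[m][:, :, iy, :].astype(float)
        g = gm.groups.index("B")
        # wherever exactly one B whisker whisks, the mean equals its angle
        n = (cls == CLASS_WHISKING).sum(axis=0)
        one = n == 1
        if one.any():
            vals = np.where(cls == CLASS_WHISKING, th, 0.0).sum(axis=0)[one]
            assert np.allclose(gm.mean_theta[g][one], vals)

    def test_mean_within_member_range(self, small_table):
        gm = group_average_maps(small_table, "column")
        t = small_table
        iy = t.yaw_index(0.0)
        for g, grp in enumerate(gm.groups):
            m = t.side_mask("left") & (t.cols == grp)
            cls = t.contact_class[m][:, :, iy, :]
            th = t.theta_impact[m][:, :, iy, :].astype(float)
            whisk = cls == CLASS_WHISKING
            th_w = np.where(whisk, th, np.nan)
            has = whisk.any(axis=0)
            with np.errstate(invalid="ignore"):
                lo = np.nanmin(th_w, axis=0)[has]
                hi = np.nanmax(th_w, axis=0)[has]
            vals = gm.mean_theta[g][has]
            assert np.all(vals >= lo - 1e-6) and np.all(vals <= hi + 1e-6)

    def test_flags_partition(self, small_table):
        gm = group_average_maps(small_table, "row")
        assert np.all(np.isnan(gm.mean_theta[gm.flags != 2]))
        assert not np.any(np.isnan(gm.mean_theta[gm.flags == 2]))

    def test_rostral_columns_contact_only_nearby(self, small_table):
        gm = group_average_maps(small_table, "column")
        md = gm.max_whisking_distance()
        assert md[6] <= 15.0

    def test_unknown_grouping(self, small_table):
        with pytest.raises(ParameterError):
            group_average_maps(small_table, "diagonal")
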