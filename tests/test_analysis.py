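"""Learning metrics: trajectory scores, potent/null, tuning, trends."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import groupweight as gw
from groupweight.analysis import fit_success_logistic

CFG = gw.DecoderConfig()


class TestTrajectoryScore:
    def test_straight_path_scores_one(self):
        traj = np.array([[0.0, 0.0], [3.5, 0.0], [7.0, 0.0]])
        assert gw.trajectory_score(traj, target_center=(7.0, 0.0)) == pytest.approx(1.0)

    def test_right_angle_path(self):
        traj = np.array([[0.0, 0.0], [3.0, 0.0], [3.0, 4.0]])
        assert gw.trajectory_score(traj, target_center=(3.0, 4.0)) == pytest.approx(1.4)

    def test_degenerate_start_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            gw.trajectory_score(np.zeros((3, 2)), target_center=(0.0, 0.0))

    @given(
        st.lists(
            st.tuples(st.floats(-10, 10), st.floats(-10, 10)), min_size=2, max_size=20
        )
    )
    def test_path_at_least_chord(self, points):
        traj = np.array(points)
        target = (12.0, 5.0)
        score = gw.trajectory_score(traj, target_center=target)
        end_chord = math.hypot(traj[-1, 0] - traj[0, 0], traj[-1, 1] - traj[0, 1])
        start_chord = math.hypot(target[0] - traj[0, 0], target[1] - traj[0, 1])
        assert score >= end_chord / start_chord - 1e-9

    def test_successful_trials_bounded_below(self, short_log):
        """Successful trials end inside the target disk, so the score is
        at least 1 - radius/distance."""
        cfg = short_log.task_cfg
        bound = 1 - cfg.target_radius / cfg.target_distance
        for tr in short_log.trials:
            if tr.success:
                score = gw.trajectory_score(tr.trajectory, target_center=tr.target_position)
                assert score >= bound - 1e-9


class TestPotentNull:
    def test_subtraction_and_summation(self):
        a = np.array([[2.0, 0.5, 1.0, 1.0]])
        out = gw.potent_null_values(a, target_angle=0.0, cfg=CFG)
        assert out.potent[0] == pytest.approx(1.5)
        assert out.null[0] == pytest.approx(2.5)

    def test_balanced_groups_zero_potent(self):
        a = np.array([[1.3, 1.3, 0.0, 0.0]])
        out = gw.potent_null_values(a, target_angle=0.0, cfg=CFG)
        assert out.potent[0] == 0.0

    def test_null_dominates_potent_pointwise(self, rng):
        a = rng.uniform(0, 3, size=(50, 4))
        for angle in (0.0, math.pi / 2, math.pi, -math.pi / 2):
            out = gw.potent_null_values(a, angle, CFG)
            assert np.all(out.null >= np.abs(out.potent) - 1e-12)

    def test_speed_filter_keeps_medium_bins(self):
        a = np.ones((4, 4))
        speeds = np.array([1.0, 5.0, 10.0, 14.0])  # v_max 15: keep 5 and 10
        out = gw.potent_null_values(a, 0.0, CFG, speeds=speeds, speed_filter=True)
        assert len(out.potent) == 2
        assert out.n_filtered_out == 2

    def test_velocity_is_w_times_potent(self, short_log):
        """Algebraic identity: on unclamped bins the decoded velocity on
        the target's axis equals w * potent."""
        checked = 0
        for tr in short_log.trials:
            a = short_log.trial_action_values(tr)
            out = gw.potent_null_values(a, tr.target_angle, short_log.decoder_cfg)
            sl = short_log.frames.iloc[tr.movement_start_bin:tr.end_bin]
            sector = gw.sector_of(tr.target_angle)
            axis = "vx" if sector in ("right", "left") else "vy"
            sign = 1.0 if sector in ("right", "up") else -1.0
            v = sl[axis].to_numpy()
            ok = np.abs(v) < short_log.decoder_cfg.v_max  # unclamped bins only
            assert np.allclose(v[ok], sign * short_log.decoder_cfg.w * out.potent[ok])
            checked += int(ok.sum())
        assert checked > 0


class TestDirectionTuning:
    def test_noiseless_cosine_recovered(self, rng):
        theta = rng.uniform(0, 2 * math.pi, 500)
        fr = 10.0 + 4.0 * np.cos(theta - math.pi / 2)
        fit = gw.fit_direction_tuning(fr, theta)
        assert fit.pd_angle == pytest.approx(math.pi / 2)
        assert fit.tuning_depth == pytest.approx(8.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_rate_zero_depth(self, rng):
        theta = rng.uniform(0, 2 * math.pi, 100)
        fit = gw.fit_direction_tuning(np.full(100, 7.0), theta)
        assert fit.tuning_depth == pytest.approx(0.0, abs=1e-9)
        assert fit.r2 == 0.0

    def test_identical_angles_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            gw.fit_direction_tuning(np.arange(10.0), np.full(10, 0.5))

    def test_poisson_pd_recovery_simulation(self):
        """Poisson data from a known PD, 2000 bins: |error| < 10 degrees
        in at least 95% of 50 replicates."""
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(50):
            pd_true = rng.uniform(-math.pi, math.pi)
            theta = rng.uniform(0, 2 * math.pi, 2000)
            lam = np.maximum(10.0 + 4.0 * np.cos(theta - pd_true), 0.0)
            fr = rng.poisson(lam * 0.1) / 0.1
            fit = gw.fit_direction_tuning(fr, theta)
            err = abs(math.remainder(fit.pd_angle - pd_true, 2 * math.pi))
            hits += math.degrees(err) < 10.0
        assert hits >= 48  # 95% of 50, rounded up


class TestPdAdDistance:
    @pytest.mark.parametrize(
        "pd, ad, expected",
        [
            (0.7, 0.7, 0.0),  # same direction
            (0.0, math.pi, 1.0),  # opposite directions
            (math.pi / 4, 0.0, 0.25),  # sector edge
        ],
    )
    def test_reference_points(self, pd, ad, expected):
        assert gw.pd_ad_distance(pd, ad) == pytest.approx(expected)

    @given(st.floats(-10, 10), st.floats(-10, 10))
    def test_symmetric_periodic_unit_interval(self, pd, ad):
        d = gw.pd_ad_distance(pd, ad)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(gw.pd_ad_distance(ad, pd))
        assert d == pytest.approx(gw.pd_ad_distance(pd + 2 * math.pi, ad), abs=1e-9)

    def test_image_covers_unit_interval(self):
        angles = np.linspace(0, math.pi, 101)
        dists = [gw.pd_ad_distance(a, 0.0) for a in angles]
        assert dists[0] == 0.0 and dists[-1] == pytest.approx(1.0)
        assert np.all(np.diff(dists) > 0)


class TestSuccessLogistic:
    def test_increasing_rates_positive_slope(self, rng):
        sess = np.repeat(np.arange(12), 100)
        p = np.repeat(np.linspace(0.1, 0.9, 12), 100)
        trend = fit_success_logistic(sess, rng.random(1200) < p)
        assert trend.slope > 0
        assert trend.slope_p < 0.001
        assert 0 < trend.pseudo_r2 < 1

    def test_all_success_flags_separation(self):
        sess = np.repeat([1, 2, 3], 10)
        trend = fit_success_logistic(sess, np.ones(30, dtype=bool))
        assert trend.separation
        assert math.isnan(trend.slope_p)

    def test_step_separation_flagged_and_penalized(self):
        sess = np.repeat(np.arange(6), 20)
        outcome = sess >= 3  # perfectly separated at session 3
        trend = fit_success_logistic(sess, outcome)
        assert trend.separation
        assert np.isfinite(trend.slope)

    def test_single_session_rejected(self):
        with pytest.raises(ValueError, match="2 sessions"):
            fit_success_logistic(np.ones(10), np.zeros(10))

    def test_null_type_one_error_calibrated(self):
        """Outcome independent of session: rejection rate at alpha=0.05
        stays within 0.05 +/- 0.03 over 500 replicates."""
        rng = np.random.default_rng(7)
        sess = np.repeat(np.arange(12), 100)
        rejections = 0
        for _ in range(500):
            trend = fit_success_logistic(sess, rng.random(1200) < 0.5)
            rejections += (not trend.separation) and trend.slope_p < 0.05
        assert 0.02 <= rejections / 500 <= 0.08

    def test_per_session_rates_returned(self, rng):
        sess = np.repeat([1, 2], 50)
        y = np.concatenate([np.zeros(50), np.ones(50)]) > 0
        y[0] = True  # avoid separation
        y[-1] = False
        trend = fit_success_logistic(sess, y)
        assert trend.per_session_success[1] == pytest.approx(0.02)
        assert trend.per_session_success[2] == pytest.approx(0.98)


class TestOccupancyAndDirections:
    def test_counts_conserved(self, rng):
        trajs = [rng.uniform(-10, 10, size=(rng.integers(5, 30), 2)) for _ in range(8)]
        edges = np.linspace(-15, 15, 31)
        grid = gw.occupancy_map(trajs, edges, edges)
        assert grid.sum() == sum(len(t) for t in trajs)

    def test_straight_trajectory_touches_only_traversed_cells(self):
        traj = np.column_stack([np.linspace(0, 7, 20), np.zeros(20)])
        edges = np.linspace(-15, 15, 31)
        grid = gw.occupancy_map([traj], edges, edges)
        ys = np.nonzero(grid)[1]
        assert set(ys) == {15}  # only the y=0 row of cells

    def test_direction_binned_success_partitions(self, short_log):
        props = gw.direction_binned_success(short_log.trials)
        assert set(props) == {"right", "up", "left", "down"}
        weights, total = 0.0, 0.0
        for lab, p in props.items():
            n = sum(gw.sector_of(t.target_angle) == lab for t in short_log.trials)
            if not math.isnan(p):
                assert 0.0 <= p <= 1.0
                weights += p * n
                total += n
        assert weights / total == pytest.approx(short_log.success_rate)

    def test_empty_quadrants_reported_missing(self):
        trials = [
            type("Tr", (), {"target_angle": 0.0, "success": True})(),
            type("Tr", (), {"target_angle": 0.1, "success": False})(),
        ]
        props = gw.direction_binned_success(trials)
        assert props["right"] == pytest.approx(0.5)
        assert math.isnan(props["up"]) and math.isnan(props["left"])
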