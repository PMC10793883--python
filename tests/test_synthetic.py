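"""Synthetic population: intent, rates, spiking, imposed learning."""

import math

import numpy as np
import pytest

import groupweight as gw
from groupweight.synthetic import SyntheticUnit


def make_unit(pd=0.0, base=10.0, depth=8.0, noise=0.0, ad=None):
    return SyntheticUnit(
        channel_id="u", baseline_rate=base, modulation_depth=depth,
        pd_angle=pd, rate_noise_sd=noise, assigned_direction=ad,
    )


class TestIntentDirection:
    def test_points_at_target(self):
        v = gw.intent_direction((0.0, 0.0), (7.0, 0.0))
        assert v == pytest.approx((1.0, 0.0))

    def test_none_when_frozen(self):
        assert gw.intent_direction((0.0, 0.0), (7.0, 0.0), frozen=True) is None

    def test_none_at_target_center(self):
        assert gw.intent_direction((7.0, 0.0), (7.0, 0.0)) is None


class TestUnitRate:
    def test_aligned_intent_peaks(self):
        assert gw.unit_rate(make_unit(pd=0.0), np.array([1.0, 0.0])) == 18.0

    def test_orthogonal_intent_baseline(self):
        assert gw.unit_rate(make_unit(pd=0.0), np.array([0.0, 1.0])) == pytest.approx(10.0)

    def test_opposite_intent_rectified(self):
        u = make_unit(pd=0.0, base=5.0, depth=8.0)
        assert gw.unit_rate(u, np.array([-1.0, 0.0])) == 0.0

    def test_no_intent_gives_baseline(self):
        assert gw.unit_rate(make_unit(), None) == 10.0

    def test_rate_mean_matches_rectified_cosine(self, rng):
        """Empirical mean of noisy rates stays within 3 SE of the
        rectified-cosine expectation at fixed intent."""
        u = make_unit(pd=0.3, noise=2.0)
        intent = np.array([math.cos(1.0), math.sin(1.0)])
        draws = np.array([gw.unit_rate(u, intent, rng) for _ in range(4000)])
        clean = 10.0 + 8.0 * math.cos(1.0 - 0.3)
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - clean) < 3 * se


class TestSampleSpikes:
    def test_zero_rate_zero_spikes(self, rng):
        assert gw.sample_spikes(0.0, rng=rng) == 0

    def test_poisson_mean(self):
        rng = np.random.default_rng(5)
        counts = [gw.sample_spikes(50.0, rng=rng) for _ in range(100_000)]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(mean - 0.5) < 3 * se

    def test_same_seed_identical_streams(self):
        a = [gw.sample_spikes(20.0, rng=np.random.default_rng(9)) for _ in range(50)]
        b = [gw.sample_spikes(20.0, rng=np.random.default_rng(9)) for _ in range(50)]
        assert a == b

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            gw.sample_spikes(-1.0)


class TestAdvanceLearning:
    def test_rotation_moves_along_shorter_arc(self):
        u = make_unit(pd=math.radians(30), ad=0.0)
        sched = gw.LearningSchedule(pd_rotation_per_session=math.radians(10),
                                    noise_decay_per_session=1.0)
        (out,) = gw.advance_learning([u], sched)
        assert math.degrees(out.pd_angle) == pytest.approx(20.0)

    def test_no_overshoot_at_fixed_point(self):
        u = make_unit(pd=0.5, ad=0.5)
        sched = gw.LearningSchedule(pd_rotation_per_session=1.0)
        (out,) = gw.advance_learning([u], sched)
        assert out.pd_angle == 0.5

    def test_null_schedule_is_fixed_point(self):
        u = make_unit(pd=1.0, ad=0.0, noise=3.0)
        (out,) = gw.advance_learning([u], gw.LearningSchedule.null())
        assert out.pd_angle == 1.0 and out.rate_noise_sd == 3.0

    def test_wraparound_takes_shorter_arc(self):
        u = make_unit(pd=math.radians(-170), ad=math.radians(170))
        sched = gw.LearningSchedule(pd_rotation_per_session=math.radians(10),
                                    noise_decay_per_session=1.0)
        (out,) = gw.advance_learning([u], sched)
        assert abs(math.degrees(out.pd_angle)) == pytest.approx(180.0)

    def test_indirect_units_untouched(self):
        u = make_unit(pd=1.0, ad=None, noise=3.0)
        sched = gw.LearningSchedule(pd_rotation_per_session=1.0, noise_decay_per_session=0.5)
        (out,) = gw.advance_learning([u], sched)
        assert out == u

    def test_pd_ad_distance_nonincreasing_over_sessions(self):
        rng = np.random.default_rng(3)
        units = gw.make_population(rng=rng)
        sched = gw.LearningSchedule()
        prev = None
        for _ in range(12):
            dists = [gw.pd_ad_distance(u.pd_angle, u.assigned_direction)
                     for u in units if u.direct]
            if prev is not None:
                assert all(d <= p + 1e-12 for d, p in zip(dists, prev))
            prev = dists
            units = gw.advance_learning(units, sched)


class TestPopulation:
    def test_default_population_layout(self):
        units = gw.make_population(rng=np.random.default_rng(0))
        assert len(units) == 32
        assert sum(u.direct for u in units) == 16
        spec = gw.population_group_spec(units)
        assert all(len(g) == 4 for g in spec.groups)

    def test_direct_pds_offset_from_ad(self):
        cfg = gw.PopulationConfig()
        units = gw.make_population(cfg, np.random.default_rng(1))
        lo, hi = cfg.pd_offset_range
        for u in units:
            if u.direct:
                off = abs(math.remainder(u.pd_angle - u.assigned_direction, 2 * math.pi))
                assert lo - 1e-9 <= off <= hi + 1e-9


class TestClosedLoop:
    def test_well_aligned_low_noise_population_controls_well(self):
        """PD = AD, low noise: the simulated user should succeed in
        over 90% of trials."""
        rng = np.random.default_rng(10)
        cfg = gw.PopulationConfig(pd_offset_range=(0.0, 1e-6), rate_noise_sd=0.5)
        units = gw.make_population(cfg, rng)
        groups = gw.population_group_spec(units)
        pre = gw.generate_idle_frame(units, 30.0, rng)
        mu, delta = gw.estimate_normalization(pre, groups, gw.DecoderConfig())
        log = gw.run_closed_loop_session(
            units, groups.with_normalization(mu, delta), gw.DecoderConfig(),
            gw.TaskConfig(), 120.0, rng, engagement=1.0,
        )
        assert len(log.trials) >= 5
        assert log.success_rate > 0.9

    def test_log_passes_schema_checks(self, short_log):
        short_log.validate()
        assert np.all(short_log.spikes.counts >= 0)
        assert len(short_log.frames) == short_log.spikes.n_bins // 10

    def test_untuned_population_at_chance(self):
        """With zero modulation depth, online success should be
        statistically indistinguishable from the shuffled baseline of
        the same log (two-proportion z-test)."""
        from scipy.stats import norm

        rng = np.random.default_rng(21)
        cfg = gw.PopulationConfig(modulation_depth=0.0, indirect_depth=0.0,
                                  rate_noise_sd=5.0)
        units = gw.make_population(cfg, rng)
        groups = gw.population_group_spec(units)
        pre = gw.generate_idle_frame(units, 30.0, rng)
        mu, delta = gw.estimate_normalization(pre, groups, gw.DecoderConfig())
        tcfg = gw.TaskConfig(variant="T", freeze_range=(0.0, 0.0), trial_timeout=10.0,
                             target_distance=2.5, target_radius=1.25)
        log = gw.run_closed_loop_session(
            units, groups.with_normalization(mu, delta), gw.DecoderConfig(),
            tcfg, 240.0, rng, engagement=1.0,
        )
        base = gw.chance_baseline([log], seed=22, n_shuffles=3)
        n1 = len(log.trials)
        k1 = sum(t.success for t in log.trials)
        n2 = base.n_trials
        k2 = round(base.mean_rate * n2)
        p = (k1 + k2) / (n1 + n2)
        if p in (0.0, 1.0):
            z = 0.0
        else:
            z = (k1 / n1 - k2 / n2) / math.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
        assert abs(z) < norm.ppf(0.995)  # not distinguishable at alpha=0.01

    def test_fixed_seed_reproducible_logs(self):
        def one(seed):
            units = gw.make_population(rng=np.random.default_rng(seed))
            logs, _ = gw.run_training(
                units, gw.LearningSchedule(), 2, gw.DecoderConfig(), gw.TaskConfig(),
                np.random.default_rng(seed + 1), session_duration=30.0,
                pre_experiment_duration=20.0,
            )
            return logs
        a, b = one(7), one(7)
        for la, lb in zip(a, b):
            assert la.spikes == lb.spikes
            assert la.frames.equals(lb.frames)
            assert len(la.trials) == len(lb.trials)
            for ta, tb in zip(la.trials, lb.trials):
                assert ta.outcome == tb.outcome
                assert np.array_equal(ta.trajectory, tb.trajectory)

    def test_normalization_chains_across_sessions(self):
        units = gw.make_population(rng=np.random.default_rng(2))
        logs, _ = gw.run_training(
            units, gw.LearningSchedule(), 3, gw.DecoderConfig(), gw.TaskConfig(),
            np.random.default_rng(3), session_duration=30.0, pre_experiment_duration=20.0,
        )
        # session 2's constants must equal a fresh estimate from its own
        # stored pre-experiment segment
        mu, delta = gw.estimate_normalization(
            logs[1].pre_experiment, logs[1].group_spec, logs[1].decoder_cfg
        )
        assert np.allclose(logs[1].group_spec.mu, mu)
        assert np.allclose(logs[1].group_spec.delta, delta)
        # and differ from session 1's idle-based constants
        assert not np.allclose(logs[0].group_spec.mu, logs[1].group_spec.mu)
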