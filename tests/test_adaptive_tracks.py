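"""Adaptive track engines: hand-traced runs, convergence against analytic
and Monte-Carlo oracles, reversal bookkeeping, bounds, and determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hearsim import (
    AdjustmentConfig,
    CriterionSpec,
    DetectionSpec,
    HWConfig,
    ProgressiveConfig,
    PsychometricSpec,
    SimpleStairConfig,
    StaircaseConfig,
    UnsupportedRuleError,
    ValidationError,
    psychometric_probability,
    run_adjustment,
    run_hughson_westlake,
    run_progressive_track,
    run_simple_staircase,
    run_transformed_staircase,
    staircase_target_proportion,
)
from hearsim.adaptive_tracks import (
    COMPLETED,
    CONSECUTIVE_NO,
    FALSE_ALARM_ABORT,
    FLOOR_REACHED,
    MAX_TRIALS,
    NO_REVERSALS,
)

from conftest import step_listener


def _recount_reversals(trials, n_down, n_up):
    """Independent recount of direction flips from the trial log."""
    consec_c = consec_i = 0
    last = 0
    count = 0
    for t in trials:
        if t.is_catch:
            continue
        d = 0
        if t.response:
            consec_c += 1
            consec_i = 0
            if consec_c == n_down:
                d, consec_c = -1, 0
        else:
            consec_i += 1
            consec_c = 0
            if consec_i == n_up:
                d, consec_i = +1, 0
        if d and last and d != last:
            count += 1
        if d:
            last = d
    return count


class TestHughsonWestlake:
    def test_hand_trace_descending_to_floor(self, rng):
        listener = DetectionSpec(step_listener(-30.0), 0.0)
        res = run_hughson_westlake(listener, HWConfig(), rng)
        levels = [t.presented_value for t in res.trials if not t.is_catch]
        assert levels == [50, 40, 30, 25, 20, 15, 10, 5, 0]
        catch = [t for t in res.trials if t.is_catch]
        assert catch and not any(t.response for t in catch)
        assert res.termination == FLOOR_REACHED
        assert res.threshold == 0.0

    def test_hand_trace_never_hearing(self, rng):
        listener = DetectionSpec(step_listener(1e6), 0.0)
        res = run_hughson_westlake(listener, HWConfig(), rng)
        levels = [t.presented_value for t in res.trials if not t.is_catch]
        assert levels == [50, 70, 80]  # +20 after first miss, then +10
        assert res.termination == CONSECUTIVE_NO
        assert math.isnan(res.threshold)

    def test_false_alarm_abort_on_fourth_false_alarm(self, rng):
        # a listener oscillating around 49 dB keeps the run alive while
        # certain catch false alarms accumulate
        listener = DetectionSpec(step_listener(49.0), 0.999999)
        res = run_hughson_westlake(listener, HWConfig(), rng)
        assert res.termination == FALSE_ALARM_ABORT
        assert res.metadata["false_alarms"] == 4
        assert math.isnan(res.threshold)

    def test_catch_trials_carry_no_level(self, rng):
        listener = DetectionSpec(step_listener(49.0), 0.5)
        res = run_hughson_westlake(listener, HWConfig(), rng)
        assert all(math.isnan(t.presented_value) for t in res.trials if t.is_catch)

    def test_requires_detection_spec(self, rng):
        with pytest.raises(ValidationError):
            run_hughson_westlake(step_listener(0.0), HWConfig(), rng)


class TestTransformedStaircase:
    def test_always_correct_descends_to_floor_without_reversals(self, rng, battery):
        cfg = battery["FM_DT"].config
        res = run_transformed_staircase(step_listener(-1e6), cfg, rng)
        values = [t.presented_value for t in res.trials]
        assert all(b <= a for a, b in zip(values, values[1:]))
        assert values[-1] == cfg.bounds[0]
        assert res.reversal_values == []
        assert res.termination == MAX_TRIALS
        assert math.isnan(res.threshold)

    def test_near_step_listener_recovers_location(self, battery):
        # mean threshold over 200 seeded runs within one stage-2 step of the
        # true location (3.0 log2 Hz)
        cfg = battery["FM_DT"].config
        listener = PsychometricSpec(3.0, 1e-3, guess_rate=0.5, lapse_rate=0.02)
        ths = [
            run_transformed_staircase(listener, cfg, np.random.default_rng(i)).threshold
            for i in range(200)
        ]
        ths = [t for t in ths if np.isfinite(t)]
        assert len(ths) >= 190
        assert abs(np.mean(ths) - 3.0) <= math.log2(2 ** 0.1)

    def test_convergence_to_transformed_updown_target(self, battery):
        # moderate-slope listeners: percent correct at the returned
        # threshold approaches 2^(-1/3) (3-down/1-up)
        cfg = battery["FM_DT"].config
        listener = PsychometricSpec(3.0, 0.5, guess_rate=0.5, lapse_rate=0.02)
        rng = np.random.default_rng(11)
        pcs = []
        for _ in range(500):
            res = run_transformed_staircase(listener, cfg, rng)
            if np.isfinite(res.threshold):
                pcs.append(psychometric_probability(listener, res.threshold))
        assert abs(np.mean(pcs) - 0.5 ** (1 / 3)) <= 0.03

    def test_stage_one_steps_five_times_stage_two_in_log_units(self, battery):
        cfg = battery["FM_DT"].config
        (s1, _), (s2, _) = cfg.stages
        assert math.log2(s1) / math.log2(s2) == pytest.approx(5.0)
        assert (math.log2(s1), math.log2(s2)) == pytest.approx((0.5, 0.1))

    def test_multiplicative_mode_rejects_nonpositive_bounds(self):
        with pytest.raises(ValidationError):
            StaircaseConfig(step_mode="multiplicative", bounds=(0.0, 100.0),
                            start_value=20.0)

    def test_threshold_is_mean_of_final_stage_reversals(self, rng, battery):
        cfg = battery["STM"].config
        listener = PsychometricSpec(2.0, 1.0, guess_rate=0.5, lapse_rate=0.02)
        res = run_transformed_staircase(listener, cfg, rng)
        assert res.termination == COMPLETED
        finals = [v for s, v in res.reversal_values if s == 1]
        assert len(finals) == 6  # "averaging the last six reversals"
        assert res.threshold == pytest.approx(np.mean(finals))


class TestSimpleStaircase:
    def test_din_always_correct_fallback(self, rng, battery):
        cfg = battery["DIN"].config
        res = run_simple_staircase(step_listener(-1e6), cfg, rng)
        levels = [t.presented_value for t in res.trials]
        assert levels == [65 - 2 * k for k in range(25)]
        assert res.termination == NO_REVERSALS
        assert res.threshold == levels[-1] - 65  # final level minus noise level

    def test_din_tracks_independent_monte_carlo_oracle(self, battery):
        # steep listener with 50% point at 45 dB SPL (TMR -20); the engine's
        # mean over 500 runs must match an independently coded random walk of
        # the same 5-up/2-down rule within 1.5 dB
        cfg = battery["DIN"].config
        listener = PsychometricSpec(45.0, 0.2, guess_rate=1e-3, lapse_rate=0.02)

        def oracle_mean(n_runs, seed):
            rng = np.random.default_rng(seed)
            outs = []
            for _ in range(n_runs):
                lvl, last, revs = 65.0, 0, []
                for _ in range(25):
                    c = rng.random() < psychometric_probability(listener, lvl)
                    d = -1 if c else 1
                    if last and d != last:
                        revs.append(lvl)
                    last = d
                    lvl = min(95.0, max(0.0, lvl + (-2.0 if c else 5.0)))
                outs.append((np.mean(revs) if revs else lvl) - 65.0)
            return float(np.mean(outs))

        engine = np.mean([
            run_simple_staircase(listener, cfg, np.random.default_rng(i)).threshold
            for i in range(500)
        ])
        assert abs(engine - oracle_mean(5000, 999)) <= 1.5

    def test_asymptotic_proportion_correct_at_din_convergence(self):
        assert staircase_target_proportion(1, 1, up_step=5, down_step=2) == pytest.approx(5 / 7)

    def test_fixed_trial_count(self, rng, battery):
        listener = PsychometricSpec(47.0, 4.0, guess_rate=1 / 32)
        res = run_simple_staircase(listener, battery["SRT"].config, rng)
        assert res.n_trials == 20


class TestProgressiveTrack:
    def test_extremes_of_the_threshold_formula(self, rng):
        cfg = ProgressiveConfig()
        all_correct = run_progressive_track(step_listener(-1e6), cfg, rng)
        assert all_correct.threshold == 11 - 22 == -11
        all_wrong = run_progressive_track(step_listener(1e6), cfg, rng)
        assert all_wrong.threshold == 11
        assert all_correct.n_trials == cfg.total_trials == 22

    def test_unbiased_for_grid_centred_listener(self):
        # symmetric logistic centred on the grid: mean threshold within
        # 0.75 dB of the 50% point over 1,000 runs
        cfg = ProgressiveConfig()
        listener = PsychometricSpec(0.0, 2.0, guess_rate=0.0, lapse_rate=0.0)
        rng = np.random.default_rng(5)
        ths = [run_progressive_track(listener, cfg, rng).threshold
               for _ in range(1000)]
        assert abs(np.mean(ths)) <= 0.75

    def test_grid_must_match_step(self):
        with pytest.raises(ValidationError):
            ProgressiveConfig(tmr_grid=(10, 7, 4), step=2.0)


class TestAdjustment:
    def test_no_jitter_returns_criterion_and_tmr(self, rng):
        listener = CriterionSpec({"masked": 68.0}, adjustment_sd=0.0)
        res = run_adjustment(listener, "masked", AdjustmentConfig(), rng)
        assert (res.level, res.tmr) == (68.0, 13.0)

    def test_clipping_at_dial_bounds(self, rng):
        listener = CriterionSpec({"uncomfortable": 90.0}, adjustment_sd=0.0)
        res = run_adjustment(listener, "uncomfortable", AdjustmentConfig(), rng)
        assert res.level == 85.0

    def test_jitter_mean_matches_criterion(self):
        listener = CriterionSpec({"comfortable": 60.0}, adjustment_sd=3.0)
        rng = np.random.default_rng(3)
        levels = [
            run_adjustment(listener, "comfortable", AdjustmentConfig(), rng).level
            for _ in range(1000)
        ]
        assert abs(np.mean(levels) - 60.0) <= 0.3

    def test_unknown_condition_rejected(self, rng):
        listener = CriterionSpec({"masked": 60.0})
        with pytest.raises(ValidationError):
            run_adjustment(listener, "loud", AdjustmentConfig(), rng)


class TestTargetProportion:
    @pytest.mark.parametrize(
        "n_down,n_up,up,down,expected",
        [
            (3, 1, 1.0, 1.0, 2 ** (-1 / 3)),
            (1, 1, 1.0, 1.0, 0.5),
            (2, 1, 1.0, 1.0, 2 ** (-1 / 2)),
            (1, 1, 5.0, 2.0, 5 / 7),
        ],
    )
    def test_analytic_targets(self, n_down, n_up, up, down, expected):
        assert staircase_target_proportion(n_down, n_up, up, down) == pytest.approx(expected)

    def test_unsupported_rule_raises(self):
        with pytest.raises(UnsupportedRuleError):
            staircase_target_proportion(3, 1, up_step=5.0, down_step=2.0)
        with pytest.raises(UnsupportedRuleError):
            staircase_target_proportion(3, 2)


class TestEngineInvariants:
    @given(loc=st.floats(-10, 15), slope=st.floats(0.05, 5), seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_staircase_values_within_bounds(self, loc, slope, seed, battery):
        cfg = battery["FM_DT"].config
        listener = PsychometricSpec(loc, slope, guess_rate=0.5, lapse_rate=0.02)
        res = run_transformed_staircase(listener, cfg, np.random.default_rng(seed))
        for t in res.trials:
            assert cfg.bounds[0] <= t.presented_value <= cfg.bounds[1]
        assert _recount_reversals(res.trials, cfg.n_down, cfg.n_up) == len(
            res.reversal_values
        ) == sum(t.reversal for t in res.trials)

    @given(loc=st.floats(-40, 120), slope=st.floats(0.1, 10), seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_simple_staircase_bounds_and_reversals(self, loc, slope, seed, battery):
        cfg = battery["DIN"].config
        listener = PsychometricSpec(loc, slope, guess_rate=1e-3, lapse_rate=0.02)
        res = run_simple_staircase(listener, cfg, np.random.default_rng(seed))
        for t in res.trials:
            assert cfg.bounds[0] <= t.presented_value <= cfg.bounds[1]
        assert _recount_reversals(res.trials, 1, 1) == len(res.reversal_values)

    @given(loc=st.floats(-20, 110), fa=st.floats(0, 0.5), seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_hughson_westlake_levels_within_bounds(self, loc, fa, seed):
        cfg = HWConfig()
        listener = DetectionSpec(PsychometricSpec(loc, 3.0, lapse_rate=0.02), fa)
        res = run_hughson_westlake(listener, cfg, np.random.default_rng(seed))
        for t in res.trials:
            if not t.is_catch:
                assert cfg.floor <= t.presented_value <= cfg.ceiling

    def test_engine_determinism(self, battery):
        cfg = battery["FM_DT"].config
        listener = PsychometricSpec(2.7, 0.5, guess_rate=0.5, lapse_rate=0.02)
        a = run_transformed_staircase(listener, cfg, np.random.default_rng(99))
        b = run_transformed_staircase(listener, cfg, np.random.default_rng(99))
        assert a.threshold == b.threshold
        assert a.trials == b.trials
        assert a.reversal_values == b.reversal_values

    def test_track_result_serialises(self, rng, battery):
        listener = PsychometricSpec(2.7, 0.5, guess_rate=0.5, lapse_rate=0.02)
        res = run_transformed_staircase(listener, battery["FM_DT"].config, rng)
        frame = res.to_frame()
        assert list(frame.columns) == ["trial", "value", "is_catch", "response",
                                       "reversal", "stage"]
        assert len(frame) == res.n_trials
        summary = res.summary()
        assert summary["termination"] == res.termination
        assert len(summary["reversal_values"]) == len(res.reversal_values)
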