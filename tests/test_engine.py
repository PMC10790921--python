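"""Engine: outcome classification rules, timeouts, AI load tracking,
stimulus statistics, and seed determinism."""

import numpy as np
import pytest

from cybervigil import (
    ActionEvent,
    TrialConfig,
    TrialState,
    WorkloadSchedule,
    generate_stimulus_stream,
    run_trial,
)
from cybervigil.engine import TrialFinishedError, ip_address
from cybervigil.io import write_trial_log


def fresh_state(mode="static", **kwargs):
    cfg = TrialConfig(schedule=WorkloadSchedule(mode=mode), seed=1, **kwargs)
    return TrialState(cfg)


class TestLeftScreen:
    def test_macro_on_active_flicker_is_hit_and_icon_reverts(self):
        state = fresh_state()
        state.record_flicker_onset(5.0, u=7 / 16, frequency=48.0)
        assert 7 in state.active_flickers
        (rec,) = state.apply_action(ActionEvent(6.0, "macro_ctrl_d"))
        assert (rec.screen, rec.outcome) == ("left", "hit")
        assert state.active_flickers == {}

    def test_macro_with_no_flicker_is_false_alarm(self):
        state = fresh_state()
        (rec,) = state.apply_action(ActionEvent(3.0, "macro_ctrl_d"))
        assert (rec.screen, rec.outcome, rec.signal_id) == ("left", "false_alarm", None)

    def test_macro_answers_oldest_active_flicker(self):
        state = fresh_state()
        first = state.record_flicker_onset(5.0, u=0.0, frequency=48.0)
        state.record_flicker_onset(6.0, u=0.0, frequency=48.0)
        (rec,) = state.apply_action(ActionEvent(7.0, "macro_ctrl_d"))
        assert rec.outcome == "hit" and rec.signal_id == first
        assert len(state.active_flickers) == 1

    def test_unanswered_flicker_times_out_as_miss(self):
        state = fresh_state()  # flicker_timeout 10 s
        state.record_flicker_onset(100.0, u=0.0, frequency=48.0)
        assert state.advance_time(109.9) == []
        (rec,) = state.advance_time(111.0)
        assert (rec.screen, rec.outcome, rec.timestamp) == ("left", "miss", 110.0)

    def test_advance_with_no_active_signals_produces_nothing(self):
        state = fresh_state()
        assert state.advance_time(1000.0) == []
        assert state.outcomes == []


class TestCenterScreen:
    def setup_queue(self, state, priority=3):
        # alert type index = priority - 1 with the default taxonomy
        return state.enqueue_alert(10.0, type_idx=priority - 1, ip_idx=2)

    def test_matching_rating_is_hit(self):
        state = fresh_state()
        sig = self.setup_queue(state, priority=3)
        (rec,) = state.apply_action(ActionEvent(12.0, "rate_alert", score=3))
        assert (rec.screen, rec.outcome, rec.signal_id) == ("center", "hit", sig)
        assert len(state.alert_queue) == 0

    def test_underrated_score_overestimates_threat_false_alarm(self):
        # numerically lower score = more severe than the alert really is
        state = fresh_state()
        self.setup_queue(state, priority=3)
        (rec,) = state.apply_action(ActionEvent(12.0, "rate_alert", score=2))
        assert (rec.screen, rec.outcome, rec.signal_id) == ("center", "false_alarm", None)

    def test_overrated_score_underestimates_threat_miss(self):
        state = fresh_state()
        self.setup_queue(state, priority=3)
        (rec,) = state.apply_action(ActionEvent(12.0, "rate_alert", score=4))
        assert (rec.screen, rec.outcome) == ("center", "miss")

    def test_rating_increments_true_type_chart_column(self):
        state = fresh_state()
        self.setup_queue(state, priority=3)
        state.apply_action(ActionEvent(12.0, "rate_alert", score=1))  # wrong rating
        assert state.columns[2][2] == 1  # chart of the TRUE type grew


class TestRightScreen:
    def grow_to_breach(self, state, chart=0, ip_idx=4):
        # priority-1 chart: threshold 3
        thr = state.config.threshold_for_chart(chart)
        for k in range(thr):
            state.enqueue_alert(10.0 + k, type_idx=chart, ip_idx=ip_idx)
            state.apply_action(ActionEvent(10.0 + k, "rate_alert", score=chart + 1))
        return thr

    def test_column_reaching_threshold_opens_breach(self):
        state = fresh_state()
        self.grow_to_breach(state)
        assert (0, 4) in state.open_breaches

    def test_correct_ip_is_hit_and_resets_column(self):
        state = fresh_state()
        self.grow_to_breach(state)
        (rec,) = state.apply_action(ActionEvent(13.0, "admin_alert", ip=ip_address(0, 4)))
        assert (rec.screen, rec.outcome) == ("right", "hit")
        assert state.columns[0][4] == 0
        assert state.open_breaches == {}

    def test_wrong_ip_is_false_alarm(self):
        state = fresh_state()
        self.grow_to_breach(state)
        (rec,) = state.apply_action(ActionEvent(13.0, "admin_alert", ip=ip_address(1, 9)))
        assert (rec.screen, rec.outcome, rec.signal_id) == ("right", "false_alarm", None)
        assert (0, 4) in state.open_breaches  # breach still open

    def test_admin_with_no_breach_is_false_alarm(self):
        state = fresh_state()
        (rec,) = state.apply_action(ActionEvent(5.0, "admin_alert", ip=ip_address(0, 0)))
        assert (rec.screen, rec.outcome) == ("right", "false_alarm")

    def test_breach_within_timeout_window_not_yet_missed(self):
        state = fresh_state()  # breach_timeout 15 s
        self.grow_to_breach(state)  # breach opens at t=12
        assert state.advance_time(26.0) == []

    def test_breach_past_timeout_is_miss_and_reset(self):
        state = fresh_state()
        self.grow_to_breach(state)  # breach opens at t=12
        (rec,) = state.advance_time(28.0)
        assert (rec.screen, rec.outcome, rec.timestamp) == ("right", "miss", 27.0)
        assert state.columns[0][4] == 0


class TestAiLoadTracking:
    def test_topup_reaches_round_half_up_target(self):
        rng = np.random.default_rng(0)
        state = fresh_state(mode="dynamic")
        u = lambda: float(rng.uniform())
        # dynamic C_load(t) = t/20 + 1: target 1 at t=0, 2 at 10 min, 4 at 50 min
        for t_min, target in [(0.0, 1), (10.0, 2), (30.0, 3), (50.0, 4)]:
            state.advance_time(t_min * 60.0)
            state.ai_topup(t_min * 60.0, u)
            assert state.near_critical == target

    def test_injections_never_cross_a_threshold(self):
        rng = np.random.default_rng(1)
        state = fresh_state()
        state.ai_topup(0.0, lambda: float(rng.uniform()))
        for chart, col in enumerate(state.columns):
            thr = state.config.threshold_for_chart(chart)
            assert all(c <= thr - 1 for c in col)
        assert state.open_breaches == {}

    def test_topup_replaces_column_consumed_by_breach(self):
        rng = np.random.default_rng(2)
        state = fresh_state()
        u = lambda: float(rng.uniform())
        state.ai_topup(0.0, u)  # static target = 4
        assert state.near_critical == 4
        # find a near-critical column and push it over the threshold
        chart, ip_idx = next(
            (ch, ip)
            for ch in range(5)
            for ip in range(15)
            if state.columns[ch][ip] == state.config.threshold_for_chart(ch) - 1
        )
        state.enqueue_alert(5.0, type_idx=chart, ip_idx=ip_idx)
        state.apply_action(ActionEvent(5.0, "rate_alert", score=chart + 1))
        assert (chart, ip_idx) in state.open_breaches
        assert state.near_critical == 3
        state.ai_topup(5.0, u)
        assert state.near_critical == 4

    def test_no_column_exceeds_threshold_without_open_breach(self):
        state = fresh_state()
        log = run_trial(state.config, _fast_operator(), operator_seed=5)
        # threshold consistency is enforced in-flight; spot-check the end state
        # by replaying: any breach-opening increment appears as a right-screen
        # hit or miss in the log, one per breach signal id
        right = [r for r in log.outcomes if r.screen == "right" and r.signal_id]
        ids = [r.signal_id for r in right]
        assert len(ids) == len(set(ids))


def _fast_operator():
    from cybervigil import OperatorParams

    return OperatorParams()


class TestStimulusStream:
    def test_timestamps_sorted_and_within_trial(self, static_config):
        stream = generate_stimulus_stream(static_config)
        ts = [e.timestamp for e in stream]
        assert ts == sorted(ts)
        assert all(0.0 <= t <= 3600.0 for t in ts)

    def test_static_flicker_onset_count_near_constant_rate_mean(self):
        # constant 16 events/min over 60 min -> Poisson mean 960
        counts = []
        for seed in range(20):
            cfg = TrialConfig(schedule=WorkloadSchedule(mode="static"), seed=seed)
            counts.append(
                sum(e.kind == "flicker_onset" for e in generate_stimulus_stream(cfg))
            )
        # se of the mean = sqrt(960/20) ~ 6.9; allow 4 se
        assert abs(np.mean(counts) - 960.0) < 28.0

    def test_dynamic_stream_contains_ai_step_injections(self, dynamic_config):
        stream = generate_stimulus_stream(dynamic_config)
        inj = [e for e in stream if e.kind == "ai_injection"]
        # initial top-up at t=0 plus one step each at 10, 30, 50 min
        assert len(inj) >= 4
        assert any(e.timestamp == 0.0 for e in inj)


class TestRunTrial:
    def test_perfect_operator_no_misses_or_false_alarms(self, perfect_operator):
        cfg = TrialConfig(schedule=WorkloadSchedule(mode="static", duration=10.0), seed=3)
        log = run_trial(cfg, perfect_operator, operator_seed=11)
        counts = log.outcome_counts()
        # a signal arriving in the last moments cannot be answered before the
        # trial ends; tolerate only that boundary case
        total_miss = sum(counts[s]["miss"] for s in counts)
        total_fa = sum(counts[s]["false_alarm"] for s in counts)
        last_events = [
            r for r in log.outcomes if r.outcome == "miss" and r.timestamp == cfg.duration_s
        ]
        assert total_fa == 0
        assert total_miss == len(last_events)
        assert counts["left"]["hit"] > 100

    def test_inert_operator_only_misses_left_signals(self, inert_operator):
        cfg = TrialConfig(schedule=WorkloadSchedule(mode="static", duration=10.0), seed=4)
        log = run_trial(cfg, inert_operator, operator_seed=12)
        counts = log.outcome_counts()
        onsets = sum(
            e.kind == "flicker_onset" and e.payload["icon"] is not None for e in log.stimuli
        )
        assert counts["left"]["hit"] == 0
        assert counts["left"]["miss"] == onsets
        assert not any(a.action in ("macro_ctrl_d", "admin_alert") for a in log.actions)
        assert counts["right"]["hit"] == 0

    def test_every_left_signal_resolves_exactly_once(self, short_static_config):
        log = run_trial(short_static_config, _fast_operator(), operator_seed=9)
        onset_ids = {
            f"L{i}"
            for i, e in enumerate(
                e for e in log.stimuli if e.kind == "flicker_onset"
            )
            if e.payload["icon"] is not None
        }
        resolved = [r.signal_id for r in log.outcomes if r.screen == "left" and r.signal_id]
        assert sorted(resolved) == sorted(onset_ids)

    def test_center_outcomes_match_rating_actions(self, short_static_config):
        log = run_trial(short_static_config, _fast_operator(), operator_seed=9)
        n_ratings = sum(a.action == "rate_alert" for a in log.actions)
        n_center = sum(r.screen == "center" for r in log.outcomes)
        assert n_center == n_ratings

    def test_identical_seeds_give_byte_identical_logs(self, short_static_config, tmp_path):
        op = _fast_operator()
        log1 = run_trial(short_static_config, op, operator_seed=21)
        log2 = run_trial(short_static_config, op, operator_seed=21)
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        write_trial_log(log1, p1)
        write_trial_log(log2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_operator_seed_changes_actions(self, short_static_config):
        op = _fast_operator()
        log1 = run_trial(short_static_config, op, operator_seed=21)
        log2 = run_trial(short_static_config, op, operator_seed=22)
        assert [a.timestamp for a in log1.actions] != [a.timestamp for a in log2.actions]

    def test_action_on_finished_trial_rejected(self, short_static_config):
        state = TrialState(short_static_config)
        state.finalize()
        with pytest.raises(TrialFinishedError):
            state.apply_action(ActionEvent(1.0, "macro_ctrl_d"))


class TestStrictMissRule:
    def test_center_action_during_flicker_scores_left_miss(self):
        state = fresh_state(strict_miss_rule=True)
        sig = state.record_flicker_onset(5.0, u=0.0, frequency=48.0)
        state.enqueue_alert(5.0, type_idx=0, ip_idx=0)
        recs = state.apply_action(ActionEvent(6.0, "rate_alert", score=1))
        left = [r for r in recs if r.screen == "left"]
        assert len(left) == 1 and left[0].outcome == "miss" and left[0].signal_id == sig


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"icon_count": 0},
            {"flicker_timeout": 0.0},
            {"breach_timeout": -1.0},
            {"admin_thresholds": {1: 3, 2: 2, 3: 7, 4: 9, 5: 11}},  # not increasing
            {"admin_thresholds": {1: 1, 2: 5, 3: 7, 4: 9, 5: 11}},  # below 2
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrialConfig(schedule=WorkloadSchedule(mode="static"), seed=1, **kwargs)
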