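"""Schedule state machines: worked examples, oracle equivalence, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from opheno import (
    PR_SERIES,
    PressStream,
    SessionConfig,
    breaking_point,
    build_pr_series,
    count_pellet_free_active,
    count_reinforcers,
    count_shocks,
    run_fr_session,
    run_pr_session,
    run_shock_session,
)
from opheno.schedules import SessionOverrunWarning, count_active_presses

from _oracles import (
    oracle_fr_walk,
    oracle_pr_completions,
    oracle_shock_walk,
    random_stream,
)


def all_active(times):
    times = np.asarray(times, dtype=float)
    return PressStream(times, np.ones(times.size, dtype=bool))


class TestPRSeries:
    def test_printed_values(self):
        series = build_pr_series()
        assert series[0] == 1
        assert series[9] == 155
        assert series[-1] == 5500
        assert len(series) == 35

    def test_strictly_increasing(self):
        assert all(b > a for a, b in zip(PR_SERIES, PR_SERIES[1:]))


class TestFRSession:
    def test_fr5_single_period_pellet_times(self, short_fr_config):
        """1 press/s for 30 s under FR5 with a 10-s time-out: pellets land on
        the 5th countable press (t=4) and again 5 presses after time-out end
        (t=18)."""
        log = run_fr_session(all_active(np.arange(30)), short_fr_config)
        pellets = [e.time_s for e in log.of_type("pellet")]
        assert pellets == [4.0, 18.0]
        assert count_reinforcers(log) == 2

    def test_empty_stream_only_markers(self, fr5_config):
        log = run_fr_session(PressStream(np.array([]), np.array([], bool)), fr5_config)
        assert count_reinforcers(log) == 0
        kinds = {e.event_type for e in log.events}
        assert kinds <= {"period_start", "period_end", "session_end"}

    def test_pellet_free_presses_earn_nothing(self, fr5_config):
        lo, _ = fr5_config.pellet_free_interval
        times = lo + np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        log = run_fr_session(all_active(times), fr5_config)
        assert count_reinforcers(log) == 0
        presses = log.of_type("active_press")
        assert len(presses) == 5
        assert all(e.countable is False for e in presses)
        assert count_pellet_free_active(log) == 5

    def test_press_at_timeout_end_counts(self, short_fr_config):
        # pellet at t=4 opens [4, 14); press exactly at 14 is countable
        times = np.array([0, 1, 2, 3, 4, 14.0])
        log = run_fr_session(all_active(times), short_fr_config)
        last = [e for e in log.of_type("active_press") if e.time_s == 14.0][0]
        assert last.countable is True

    def test_counter_persists_across_pellet_free_period(self):
        cfg = SessionConfig(session_kind="fr", fixed_ratio=5,
                            pellet_period_1_s=100.0, pellet_free_s=50.0,
                            pellet_period_2_s=100.0)
        times = np.array([10, 20, 30, 160.0, 170.0])  # 3 + 2 countable
        log = run_fr_session(all_active(times), cfg)
        assert [e.time_s for e in log.of_type("pellet")] == [170.0]

    def test_overrun_presses_dropped_with_warning(self, short_fr_config):
        with pytest.warns(SessionOverrunWarning):
            log = run_fr_session(all_active([1.0, 59.0, 61.0]), short_fr_config)
        assert count_active_presses(log) == 2

    def test_wrong_kind_rejected(self, short_fr_config):
        with pytest.raises(ValueError):
            run_fr_session(all_active([1.0]), short_fr_config.with_kind("pr"))


class TestFROracleEquivalence:
    # streams deliberately overrun the session end to exercise dropping
    pytestmark = pytest.mark.filterwarnings(
        "ignore::opheno.schedules.SessionOverrunWarning"
    )

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_random_streams_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cfg = SessionConfig(
            session_kind="fr",
            fixed_ratio=int(rng.integers(1, 7)),
            pellet_period_1_s=120.0,
            pellet_free_s=float(rng.choice([0.0, 60.0])),
            pellet_period_2_s=float(rng.choice([0.0, 120.0])),
            timeout_s=float(rng.choice([5.0, 10.0])),
        )
        times, active = random_stream(rng, int(rng.integers(0, 120)),
                                      cfg.fr_session_duration_s * 1.05)
        log = run_fr_session(PressStream(times, active), cfg)
        oracle = oracle_fr_walk(
            times, active, ratio=cfg.fixed_ratio, timeout_s=cfg.timeout_s,
            p1=cfg.pellet_period_1_s, free=cfg.pellet_free_s,
            p2=cfg.pellet_period_2_s,
        )
        got_presses = [
            (e.time_s, "active" if e.event_type == "active_press" else "inactive",
             bool(e.countable))
            for e in log.of_type("active_press", "inactive_press")
        ]
        assert got_presses == [(t, lv, c) for t, lv, c in oracle["presses"]]
        assert [e.time_s for e in log.of_type("pellet")] == oracle["pellets"]

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_pellet_count_consistent_with_countable_presses(self, seed):
        rng = np.random.default_rng(seed)
        cfg = SessionConfig(session_kind="fr", fixed_ratio=int(rng.integers(1, 6)),
                            pellet_period_1_s=200.0, pellet_free_s=50.0,
                            pellet_period_2_s=200.0)
        times, active = random_stream(rng, 80, cfg.fr_session_duration_s)
        log = run_fr_session(PressStream(times, active), cfg)
        n_countable = count_active_presses(log, countable_only=True)
        n_pellets = count_reinforcers(log)
        assert n_pellets == n_countable // cfg.fixed_ratio
        lo, hi = cfg.pellet_free_interval
        for e in log.of_type("pellet"):
            assert not (lo <= e.time_s < hi)


class TestPRSession:
    def test_policy_emitting_18_presses_completes_three_ratios(self):
        emitted = {"total": 0}

        def policy(requirement, idx):
            if emitted["total"] + requirement > 18:
                return []
            emitted["total"] += requirement
            return [1.0] * requirement

        log = run_pr_session(policy)
        assert count_reinforcers(log) == oracle_pr_completions(18, PR_SERIES) == 3
        assert breaking_point(log) == 12
        end = log.events[-1].time_s
        last_press = max(e.time_s for e in log.of_type("active_press"))
        assert end == pytest.approx(last_press + 3600.0)  # inactivity cutoff

    def test_silent_policy_ends_at_inactivity_limit(self):
        log = run_pr_session(lambda req, idx: [])
        assert count_reinforcers(log) == 0
        assert log.events[-1].time_s == pytest.approx(3600.0)

    def test_unbounded_policy_ends_at_five_hour_cap(self):
        log = run_pr_session(lambda req, idx: [1.0] * req)
        assert log.events[-1].time_s == pytest.approx(5 * 3600.0)
        assert count_reinforcers(log) < len(PR_SERIES)

    def test_breaking_point_convention_and_bounds(self):
        assert breaking_point(0) == 0
        assert breaking_point(2) == 5
        assert breaking_point(35) == 5500
        with pytest.raises(ValueError):
            breaking_point(36)

    @pytest.mark.parametrize("presses", [0, 1, 6, 18, 40, 120])
    def test_completions_match_cumulative_sum_oracle(self, presses):
        budget = {"left": presses}

        def policy(requirement, idx):
            if budget["left"] < requirement:
                return []
            budget["left"] -= requirement
            return [0.5] * requirement

        log = run_pr_session(policy)
        assert count_reinforcers(log) == oracle_pr_completions(presses, PR_SERIES)

    def test_breaking_point_monotone_in_presses(self):
        bps = []
        for presses in [0, 1, 5, 17, 18, 19, 50, 200]:
            n = oracle_pr_completions(presses, PR_SERIES)
            bps.append(breaking_point(n))
        assert bps == sorted(bps)


class TestShockSession:
    def test_dense_pressing_two_shocks_per_block(self, shock_config):
        times = np.arange(0.0, shock_config.shock_session_duration_s, 2.0)
        log = run_shock_session(all_active(times), shock_config)
        assert count_shocks(log) == 2 * count_reinforcers(log)
        oracle = oracle_shock_walk(
            times, np.ones(times.size, bool), ratio=5,
            timeout_s=shock_config.timeout_s,
            duration=shock_config.shock_session_duration_s,
            window_s=shock_config.shock_fifth_response_window_s,
        )
        assert [e.time_s for e in log.of_type("shock")] == oracle["shocks"]
        assert [e.time_s for e in log.of_type("pellet")] == oracle["pellets"]

    def test_four_presses_then_silence_one_shock_no_pellet(self, shock_config):
        log = run_shock_session(all_active([1.0, 2.0, 3.0, 4.0]), shock_config)
        assert count_shocks(log) == 1
        assert count_reinforcers(log) == 0

    def test_empty_stream(self, shock_config):
        log = run_shock_session(PressStream(np.array([]), np.array([], bool)),
                                shock_config)
        assert count_shocks(log) == 0 and count_reinforcers(log) == 0

    def test_block_reset_after_missed_fifth_response(self, shock_config):
        # 4 presses, then a 61-s pause: block resets, and the 4th press of the
        # new block delivers a shock again
        times = np.array([1.0, 2.0, 3.0, 4.0, 70.0, 71.0, 72.0, 73.0])
        log = run_shock_session(all_active(times), shock_config)
        assert [e.time_s for e in log.of_type("shock")] == [4.0, 73.0]
        assert count_reinforcers(log) == 0

    @pytest.mark.filterwarnings("ignore::opheno.schedules.SessionOverrunWarning")
    @settings(max_examples=120, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_random_streams_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cfg = SessionConfig(session_kind="shock", fixed_ratio=5,
                            shock_session_duration_s=600.0)
        times, active = random_stream(rng, int(rng.integers(0, 150)), 620.0)
        log = run_shock_session(PressStream(times, active), cfg)
        oracle = oracle_shock_walk(times, active, ratio=5, timeout_s=10.0,
                                   duration=600.0, window_s=60.0)
        assert [e.time_s for e in log.of_type("shock")] == oracle["shocks"]
        assert [e.time_s for e in log.of_type("pellet")] == oracle["pellets"]
        got = [(e.time_s, bool(e.countable))
               for e in log.of_type("active_press")]
        want = [(t, c) for t, lv, c in oracle["presses"] if lv == "active"]
        assert got == want
        # structural bounds: every pellet needs both punished presses
        assert count_shocks(log) >= count_reinforcers(log)


class TestEventLogInvariants:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_times_nondecreasing_and_no_timeout_pellets(self, seed):
        rng = np.random.default_rng(seed)
        cfg = SessionConfig(session_kind="fr", fixed_ratio=3,
                            pellet_period_1_s=150.0, pellet_free_s=60.0,
                            pellet_period_2_s=150.0)
        times, active = random_stream(rng, 100, cfg.fr_session_duration_s)
        log = run_fr_session(PressStream(times, active), cfg)
        ts = [e.time_s for e in log.events]
        assert ts == sorted(ts)
        # no pellet inside any time-out interval opened by an earlier pellet
        pellet_times = [e.time_s for e in log.of_type("pellet")]
        for i, tp in enumerate(pellet_times):
            for prev in pellet_times[:i]:
                assert not (prev <= tp < prev + cfg.timeout_s)
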