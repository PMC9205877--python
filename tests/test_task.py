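"""Task engine: opponents, schedules, policies, payoffs and expectations."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from coopddm.task import (
    Choice,
    ConfigError,
    DataError,
    UnsupportedPolicyError,
    DEFAULT_PAYOFF,
    PayoffMatrix,
    OpponentSpec,
    build_opponents,
    expected_session_points,
    max_expected_session_points,
    opponent_decide,
    play_session,
    schedule_session,
)


class TestOpponents:
    def test_default_roster(self, opponents):
        assert len(opponents) == 8
        by_class = {}
        for o in opponents:
            by_class.setdefault(o.opponent_class, []).append(o.policy)
        assert sorted(by_class) == ["computer", "human"]
        for policies in by_class.values():
            assert sorted(policies) == ["cooperative", "deceitful", "random", "titfortat"]

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            build_opponents(p_cooperative=1.2)
        with pytest.raises(ConfigError):
            OpponentSpec("x", "human", "random", p_cooperate=-0.1)

    def test_deterministic_construction(self):
        assert build_opponents() == build_opponents()


class TestSchedule:
    def test_length_and_counts(self, opponents):
        sched = schedule_session(opponents, np.random.default_rng(0))
        assert len(sched) == 120
        ids = [s[1] for s in sched]
        for o in opponents:
            assert ids.count(o.id) == 15
        assert [s[0] for s in sched] == list(range(1, 121))

    def test_two_seeds_same_multiset_different_order(self, opponents):
        s1 = schedule_session(opponents, np.random.default_rng(1))
        s2 = schedule_session(opponents, np.random.default_rng(2))
        assert sorted(x[1] for x in s1) == sorted(x[1] for x in s2)
        assert [x[1] for x in s1] != [x[1] for x in s2]
        assert {x[2] for x in s1} == {"subject_first", "opponent_first"}


class TestOpponentDecide:
    def test_titfortat_replicates_last_valid_choice(self):
        spec = OpponentSpec("t", "human", "titfortat")
        rng = np.random.default_rng(0)
        hist = [(Choice.COOPERATE, Choice.COOPERATE), (None, Choice.COOPERATE)]
        assert opponent_decide(spec, hist, rng) is Choice.COOPERATE
        hist = [(Choice.DECEIVE, Choice.COOPERATE)]
        assert opponent_decide(spec, hist, rng) is Choice.DECEIVE

    def test_first_move_conventions(self):
        rng = np.random.default_rng(0)
        coop = OpponentSpec("t", "human", "titfortat", tft_first_move="cooperate")
        dec = OpponentSpec("t", "human", "titfortat", tft_first_move="deceive")
        mirror = OpponentSpec("t", "human", "titfortat", tft_first_move="mirror")
        assert opponent_decide(coop, [], rng) is Choice.COOPERATE
        assert opponent_decide(dec, [], rng) is Choice.DECEIVE
        assert opponent_decide(mirror, [], rng, subject_current=Choice.DECEIVE) is Choice.DECEIVE
        # a missing (invalid) subject response falls back to cooperation
        assert opponent_decide(mirror, [], rng, subject_current=None) is Choice.COOPERATE
        with pytest.raises(DataError):
            opponent_decide(mirror, [], rng)

    @pytest.mark.parametrize("policy,p", [("cooperative", 0.7), ("deceitful", 0.3), ("random", 0.5)])
    def test_stochastic_policy_frequencies(self, policy, p):
        """Long-run cooperation rates converge to the configured
        probabilities within a 3-sigma binomial bound at n = 1e5."""
        spec = OpponentSpec("s", "computer", policy, p_cooperate=p)
        rng = np.random.default_rng(12345)
        n = 100_000
        k = sum(opponent_decide(spec, [], rng) is Choice.COOPERATE for _ in range(n))
        assert abs(k / n - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestPlaySession:
    @staticmethod
    def _always(choice, rt=0.8):
        return lambda spec, hist: (choice, rt)

    def test_opponent_rts_within_bounds_and_points_conserved(self, opponents):
        rng = np.random.default_rng(3)
        sched = schedule_session(opponents, rng)
        trials = play_session(self._always(Choice.DECEIVE), opponents, sched, DEFAULT_PAYOFF, rng)
        assert len(trials) == 120
        assert all(1.0 <= t.opponent_rt <= 3.0 for t in trials)
        assert trials[-1].cumulative_points == sum(t.points_subject for t in trials)

    def test_nonpositive_rt_rejected(self, opponents):
        rng = np.random.default_rng(3)
        sched = schedule_session(opponents, rng)
        with pytest.raises(DataError):
            play_session(self._always(Choice.COOPERATE, rt=0.0), opponents, sched, DEFAULT_PAYOFF, rng)

    def test_invalid_trials_score_nothing(self, opponents):
        rng = np.random.default_rng(4)
        sched = schedule_session(opponents, rng)

        def flaky(spec, hist):
            return (None, 0.5) if len(hist) == 0 else (Choice.COOPERATE, 0.5)

        trials = play_session(flaky, opponents, sched, DEFAULT_PAYOFF, rng)
        invalid = [t for t in trials if not t.valid]
        assert len(invalid) == 8  # first encounter with each opponent
        assert all(t.points_subject == 0 for t in invalid)

    def test_timeout_marks_invalid(self, opponents):
        rng = np.random.default_rng(5)
        sched = schedule_session(opponents, rng)
        trials = play_session(self._always(Choice.COOPERATE, rt=11.0), opponents, sched,
                              DEFAULT_PAYOFF, rng, time_limit_s=10.0)
        assert all(not t.valid for t in trials)

    def test_tit_for_tat_sequence_fully_determined(self, opponents):
        rng = np.random.default_rng(6)
        sched = schedule_session(opponents, rng)
        seq = [Choice.COOPERATE if i % 3 else Choice.DECEIVE for i in range(120)]
        it = iter(seq)
        record = {}

        def agent(spec, hist):
            c = next(it)
            record.setdefault(spec.id, []).append(c)
            return c, 0.7

        trials = play_session(agent, opponents, sched, DEFAULT_PAYOFF, rng)
        for t in (x for x in trials if x.opponent_policy == "titfortat"):
            played = record[t.opponent_id]
            k = sum(1 for x in trials if x.opponent_id == t.opponent_id
                    and x.trial_index <= t.trial_index) - 1
            expected = played[k] if k == 0 else played[k - 1]  # mirror first, then replicate
            assert t.opponent_choice is expected


class TestExpectedPoints:
    def test_documented_session_totals(self, opponents):
        """Always-deceive earns 1725 and always-cooperate 1500 expected
        points against the default roster and payoff matrix."""
        assert expected_session_points("always_deceive", opponents, DEFAULT_PAYOFF) == 1725.0
        assert expected_session_points("always_cooperate", opponents, DEFAULT_PAYOFF) == 1500.0

    def test_myopic_best_response_total(self, opponents):
        assert max_expected_session_points(opponents, DEFAULT_PAYOFF) == 2175.0
        assert max_expected_session_points(opponents, DEFAULT_PAYOFF, mode="lookahead") >= 2175.0

    def test_constant_payoff_gives_constant_total(self, opponents):
        flat = PayoffMatrix(cc=7, cd=7, dc=7, dd=7)
        for policy in ("always_deceive", "always_cooperate"):
            assert expected_session_points(policy, opponents, flat) == 120 * 7

    def test_unsupported_policy_rejected(self, opponents):
        with pytest.raises(UnsupportedPolicyError):
            expected_session_points("titfortat_myself", opponents, DEFAULT_PAYOFF)

    def test_monte_carlo_agreement(self, opponents):
        """Simulated mean session totals agree with the closed form within
        3 standard errors (300 sessions per policy)."""
        for policy, choice in (("always_deceive", Choice.DECEIVE),
                               ("always_cooperate", Choice.COOPERATE)):
            totals = []
            for s in range(300):
                rng = np.random.default_rng(50_000 + s)
                sched = schedule_session(opponents, rng)
                trials = play_session(lambda sp, h: (choice, 0.8), opponents, sched,
                                      DEFAULT_PAYOFF, rng)
                totals.append(trials[-1].cumulative_points)
            exp = expected_session_points(policy, opponents, DEFAULT_PAYOFF)
            se = np.std(totals, ddof=1) / np.sqrt(len(totals))
            assert abs(np.mean(totals) - exp) < 3 * se

    @given(
        cc=st.integers(0, 40), cd=st.integers(0, 40),
        dc_extra=st.integers(1, 20), dd_extra=st.integers(1, 20),
    )
    def test_dominance_implies_deceive_beats_cooperate_vs_stochastic(self, cc, cd, dc_extra, dd_extra):
        """Cell-wise dominance makes always-deceive strictly better than
        always-cooperate against every stochastic opponent (tit-for-tat is
        the deliberate exception: mutual choices differ there)."""
        pm = PayoffMatrix(cc=cc, cd=cd, dc=cc + dc_extra, dd=cd + dd_extra)
        pm.check_deception_dominant()
        stochastic = [o for o in build_opponents() if o.policy != "titfortat"]
        assert (expected_session_points("always_deceive", stochastic, pm)
                > expected_session_points("always_cooperate", stochastic, pm))

    def test_default_matrix_deceive_beats_cooperate_overall(self, opponents):
        assert (expected_session_points("always_deceive", opponents, DEFAULT_PAYOFF)
                > expected_session_points("always_cooperate", opponents, DEFAULT_PAYOFF))

    def test_dominance_check_rejects_violations(self):
        with pytest.raises(ConfigError):
            PayoffMatrix(cc=20, cd=0, dc=15, dd=5).check_deception_dominant()
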