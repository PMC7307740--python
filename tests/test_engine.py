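import itertools

import numpy as np
import pandas as pd
import pytest

from crl_exes.adaptive import ACTIONS, ActorCritic
from crl_exes.arena import ArenaConfig
from crl_exes.engine import (
    Condition,
    PayoffScheme,
    logs_from_frame,
    logs_to_frame,
    make_condition,
    play_dyad,
    play_round_ballistic,
    play_round_dynamic,
    read_log_csv,
    write_log_csv,
)
from crl_exes.reactive import ReactiveConfig

HIGH = PayoffScheme(4, 1)


def fixed_agent(action):
    """An agent whose policy is (numerically) glued to one action."""
    a = ActorCritic()
    a.policy.C[ACTIONS.index(action), :] = 1e12
    a.policy.refresh()
    return a


class TestBallisticRounds:
    def test_same_choice_is_a_tie_paying_zero(self):
        rng = np.random.default_rng(0)
        out = play_round_ballistic(fixed_agent("go_high"), fixed_agent("go_high"),
                                   HIGH, rng)
        assert out.tie and (out.reward_a, out.reward_b) == (0.0, 0.0)
        assert (out.state_a, out.state_b) == ("tie", "tie")

    def test_complementary_choices_pay_both_spots(self):
        rng = np.random.default_rng(0)
        out = play_round_ballistic(fixed_agent("go_high"), fixed_agent("go_low"),
                                   HIGH, rng)
        assert not out.tie
        assert (out.reward_a, out.reward_b) == (4.0, 1.0)
        assert (out.state_a, out.state_b) == ("high", "low")

    def test_double_none_ties_half_the_time(self):
        rng = np.random.default_rng(12)
        a, b = fixed_agent("none"), fixed_agent("none")
        n = 4000
        ties = sum(play_round_ballistic(a, b, HIGH, rng).tie for _ in range(n))
        # exact enumeration of the two coins gives P(tie) = 1/2
        assert abs(ties / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_matches_matrix_game_enumeration_for_fixed_policies(self):
        # empirical outcome distribution under fixed mixed policies must
        # match the brute-force enumeration over joint actions and coins
        pa = np.array([0.5, 0.2, 0.3])
        pb = np.array([0.1, 0.6, 0.3])

        def spot_probs(p):  # P(high spot), P(low spot)
            return p[0] + 0.5 * p[2], p[1] + 0.5 * p[2]

        ah, al = spot_probs(pa)
        bh, bl = spot_probs(pb)
        expected = {
            "tie": ah * bh + al * bl,
            "a_high": ah * bl,
            "b_high": al * bh,
        }

        a, b = ActorCritic(), ActorCritic()
        # Laplace-invert the target probabilities into counts: C = k*p/(1-?) —
        # use large counts proportional to p so P -> p
        a.policy.C[:, :] = (pa * 1e9)[:, None]
        b.policy.C[:, :] = (pb * 1e9)[:, None]
        a.policy.refresh(), b.policy.refresh()
        rng = np.random.default_rng(5)
        n = 6000
        counts = {"tie": 0, "a_high": 0, "b_high": 0}
        for _ in range(n):
            out = play_round_ballistic(a, b, HIGH, rng)
            key = "tie" if out.tie else ("a_high" if out.state_a == "high" else "b_high")
            counts[key] += 1
        for key, p in expected.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[key] / n - p) < 4 * se


class TestDynamicRounds:
    def test_complementary_masks_mostly_produce_clean_outcomes(self):
        cfg, rcfg = ArenaConfig(), ReactiveConfig()
        rng = np.random.default_rng(2)
        outs = [
            play_round_dynamic(None, None, HIGH, cfg, rcfg, rng,
                               forced_actions=("go_high", "go_low"))
            for _ in range(25)
        ]
        assert all(o.steps > 0 for o in outs)
        clean = [o for o in outs if not o.tie]
        assert len(clean) >= 0.7 * len(outs)
        assert all({o.state_a, o.state_b} == {"high", "low"} for o in clean)

    def test_avoidance_lowers_contested_tie_rate(self):
        # both agents uncommitted from mirrored starts: with the avoidance
        # reflex silenced (zero gain) every contest collapses onto the big
        # spot and ties; with avoidance on, a fraction resolves cleanly
        rcfg = ReactiveConfig()
        rates = {}
        for gain in (1.0, 0.0):
            cfg = ArenaConfig(avoid_gain=gain)
            rng = np.random.default_rng(99)
            ties = sum(
                play_round_dynamic(None, None, HIGH, cfg, rcfg, rng,
                                   forced_actions=("none", "none")).tie
                for _ in range(120)
            )
            rates[gain] = ties / 120
        assert rates[1.0] < rates[0.0]

    def test_round_pays_both_spots_or_nothing(self):
        cfg, rcfg = ArenaConfig(), ReactiveConfig()
        rng = np.random.default_rng(3)
        for pair in itertools.product(("go_high", "go_low", "none"), repeat=2):
            out = play_round_dynamic(None, None, HIGH, cfg, rcfg, rng,
                                     forced_actions=pair)
            if out.tie:
                assert out.reward_a == out.reward_b == 0.0
            else:
                assert out.reward_a + out.reward_b == HIGH.a + HIGH.b
                assert {out.state_a, out.state_b} == {"high", "low"}


class TestDyads:
    def test_zero_rounds_gives_empty_log(self):
        log = play_dyad(Condition("ballistic", HIGH, 0), seed=1)
        assert len(log) == 0

    def test_same_seed_reproduces_identical_logs(self):
        cond = make_condition("dynamic", "high", rounds=6)
        assert play_dyad(cond, seed=11) == play_dyad(cond, seed=11)

    def test_different_seeds_differ(self):
        cond = make_condition("ballistic", "high", rounds=30)
        assert play_dyad(cond, 1).outcomes != play_dyad(cond, 2).outcomes

    def test_outcome_states_feed_next_round_as_previous_state(self, monkeypatch):
        seen = []
        orig = ActorCritic.choose

        def spy(self, rng):
            seen.append(self.state)
            return orig(self, rng)

        monkeypatch.setattr(ActorCritic, "choose", spy)
        cond = make_condition("ballistic", "high", rounds=8)
        log = play_dyad(cond, seed=4)
        states_a = seen[0::2]
        assert states_a[0] == "tie"  # neutral initial state
        assert states_a[1:] == [o.state_a for o in log.outcomes[:-1]]

    def test_adaptive_only_ablation_is_exactly_ballistic_play(self):
        bal = play_dyad(make_condition("ballistic", "high", rounds=40), seed=9)
        abl = play_dyad(
            make_condition("dynamic", "high", rounds=40, ablation="adaptive_only"),
            seed=9,
        )
        assert bal.outcomes == abl.outcomes

    def test_reactive_only_logs_none_actions_and_never_learns(self):
        cond = make_condition("dynamic", "high", rounds=5, ablation="reactive_only")
        log = play_dyad(cond, seed=2)
        assert all(o.action_a == o.action_b == "none" for o in log.outcomes)
        assert all(o.none_a and o.none_b for o in log.outcomes)

    def test_default_round_counts(self):
        assert make_condition("ballistic", "high").rounds == 50
        assert make_condition("ballistic", "low").rounds == 60

    def test_ablation_requires_dynamic_mode(self):
        with pytest.raises(ValueError, match="dynamic"):
            Condition("ballistic", HIGH, 10, "reactive_only")


class TestPayoffs:
    def test_presets(self):
        assert PayoffScheme(4, 1).name == "high"
        assert PayoffScheme(2, 1).name == "low"
        assert PayoffScheme(32, 1).name == "32-1"

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            PayoffScheme(1, 2)
        PayoffScheme(1, 1)  # equal payoffs allowed (sweep endpoint)


class TestLogIO:
    def test_csv_roundtrip_preserves_rounds(self, tmp_path):
        cond = make_condition("ballistic", "low", rounds=12)
        logs = [play_dyad(cond, s, dyad_id=i) for i, s in enumerate((5, 6))]
        path = write_log_csv(logs, tmp_path / "rounds.csv", config={"seed": 5})
        df = read_log_csv(path)
        assert len(df) == 24
        back = logs_from_frame(df)
        assert [l.outcomes for l in back] == [l.outcomes for l in logs]
        assert (tmp_path / "rounds.config.json").exists()

    def test_frame_schema_is_canonical(self):
        cond = make_condition("dynamic", "high", rounds=2)
        df = logs_to_frame([play_dyad(cond, 3)])
        assert list(df.columns) == [
            "dyad_id", "condition", "mode", "payoff_a", "payoff_b", "ablation",
            "seed", "round", "action_a", "action_b", "state_a", "state_b",
            "reward_a", "reward_b", "tie", "steps", "none_a", "none_b",
        ]

    def test_missing_columns_rejected(self, tmp_path):
        pd.DataFrame({"dyad_id": [1]}).to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ValueError, match="missing"):
            read_log_csv(tmp_path / "bad.csv")
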