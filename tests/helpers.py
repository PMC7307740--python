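"""Shared builders for synthetic dyad logs."""

from crl_exes.engine import Condition, DyadLog, PayoffScheme, RoundOutcome


def log_from_symbols(symbols, payoff=PayoffScheme(4, 1), mode="ballistic",
                     actions=None, dyad_id=0, seed=0):
    """Build a synthetic DyadLog from outcome symbols 'A'/'B'/'.' (tie).

    ``actions`` optionally supplies per-round (action_a, action_b) pairs;
    by default winners are logged as committed actions and ties as both
    going high.
    """
    outcomes = []
    for i, s in enumerate(symbols):
        if s == "A":
            st, rw = ("high", "low"), (payoff.a, payoff.b)
        elif s == "B":
            st, rw = ("low", "high"), (payoff.b, payoff.a)
        elif s == ".":
            st, rw = ("tie", "tie"), (0.0, 0.0)
        else:
            raise ValueError(s)
        if actions is not None:
            act = actions[i]
        elif s == ".":
            act = ("go_high", "go_high")
        else:
            act = ("go_high", "go_low") if s == "A" else ("go_low", "go_high")
        outcomes.append(
            RoundOutcome(i, act[0], act[1], st[0], st[1], rw[0], rw[1],
                         s == ".", 0, act[0] == "none", act[1] == "none")
        )
    cond = Condition(mode, payoff, len(outcomes))
    return DyadLog(dyad_id, cond, seed, outcomes)
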