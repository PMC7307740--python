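"""One embodied round driven purely by reflexes.

Two agents with no learning layer (both reward attractions plus collision
avoidance active) are dropped at their mirrored start poses and steered by
their proximity sensors until one touches a reward spot.  Prints the
outcome and where the trailing agent stood, which decides tie vs. clean
coordination.
"""
import math

import numpy as np

from crl_exes import ArenaConfig, PayoffScheme, ReactiveConfig, play_round_dynamic

rng = np.random.default_rng(7)
cfg, rcfg = ArenaConfig(), ReactiveConfig()
payoff = PayoffScheme(4, 1)

for i in range(5):
    out = play_round_dynamic(None, None, payoff, cfg, rcfg, rng,
                             forced_actions=("none", "none"))
    verdict = "tie (both contested the same spot)" if out.tie else (
        f"clean: A got {out.state_a} (+{out.reward_a:g}), "
        f"B got {out.state_b} (+{out.reward_b:g})"
    )
    print(f"round {i}: {out.steps:4d} steps -> {verdict}")

print("\nA tie pays nobody; a clean round pays out the full",
      f"{payoff.a + payoff.b:g} points between the two agents.")
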