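"""A dyad of TD learners playing the discrete (ballistic) game.

Each round both agents sample go-high / go-low / none from their Laplace
policies, outcomes resolve as the matrix game (same spot = tie = 0), and
one actor-critic update per agent follows.  Prints the outcome strip and
the final policy of agent A: columns are the previous-round states.
"""
import numpy as np

from crl_exes import make_condition, play_dyad
from crl_exes.metrics import dyad_metrics, outcome_symbols

cond = make_condition("ballistic", "high")  # payoffs 4/1, 50 rounds
log = play_dyad(cond, seed=11)

strip = "".join({"a_high": "A", "b_high": "B", "tie": "."}[s]
                for s in outcome_symbols(log))
print("outcomes (A/B = who took the high spot, . = tie):")
print(" ", strip)
m = dyad_metrics(log)
print(f"\nefficiency {m['efficiency']:.2f} (1 = no ties), "
      f"fairness {m['fairness']:.2f} (1 = even split), "
      f"stability {m['stability']:.2f} nats (lower = more predictable)")
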