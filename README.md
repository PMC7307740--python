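# crl-exes

A simulator and analysis toolkit for studying how **social conventions** form
between two embodied learning agents playing the **Battle of the Exes**, a
repeated anti-coordination game: two reward spots pay `a` (high) and `b` (low)
with `a >= b > 0`, and a round in which both players contest the same spot
pays nothing to either. The interesting question is not one round but fifty:
do a pair of agents settle into turn-taking, dominance, or no convention at
all — and how do real-time sensorimotor dynamics change the answer?

Each agent is a **control-based reinforcement learning (CRL)** architecture
with two layers:

* a **reactive layer** of pre-wired Braitenberg control laws acting at every
  simulation step — attraction to the reward spots
  (`m_left = f + s_right − s_left`, `m_right = f + s_left − s_right`) and
  repulsion from the other agent (the crossed/direct connections reversed) —
  over six proximity sensors (high spot, low spot, other agent; left/right);
* an **adaptive layer** choosing once per round among three actions
  (*go-high*, *go-low*, *none*) from three states (the previous round's
  outcome: *high*, *low*, *tie*) by tabular actor–critic TD learning:

  ```
  e_t = r_t + γ V(s_t) − V(s_prev)            TD error        (γ = 0.40)
  V(s_prev) ← V(s_prev) + η e_t               critic          (η = 0.15)
  C(a_t, s_prev) ← max(0, C + δ e_t)          actor counts    (δ = 0.45)
  P(a|s) = (C(a,s) + 1) / (Σ_a C(a,s) + 3)    Laplace's law of succession
  ```

  The chosen action feeds an **inhibitor**: *go-high* switches the low-reward
  attraction off, *go-low* switches the high-reward attraction off, *none*
  leaves every reflex active. Collision avoidance is never inhibited.

The game runs in two modes: **ballistic** (one-shot discrete choices, the
pure matrix game — only the adaptive layer acts) and **dynamic** (rounds play
out in a continuous 2D arena and agents can alter course until a spot is
reached). Dyads are scored by **efficiency** (collective reward / maximum
possible, equal to the non-tie fraction), **fairness**
(`1 − |n_a − n_b| / (n_a + n_b)` over high-reward acquisitions) and
**stability** — the mean *surprisal* (negative log-probability, in nats, of
each round's outcome under a sliding-window empirical predictor; lower =
more predictable = more stable).

## A worked example

```
$ python examples/02_ballistic_learning.py
outcomes (A/B = who took the high spot, . = tie):
  B...A.BBBB...BB.....B..BB.AB...B.BAB....A..B.B..A.

efficiency 0.42 (1 = no ties), fairness 0.48 (1 = even split), stability 1.01 nats (lower = more predictable)
```

One dyad of TD learners plays 50 ballistic rounds at payoffs 4/1. The strip
shows who reached the high spot each round; this pair drifted toward B-side
dominance (fairness 0.48) while still colliding in over half the rounds
(efficiency 0.42), and its outcomes were moderately predictable (1.01 nats
against the 1.10-nat cost of a uniform 3-symbol guess).

Other examples (each runs in seconds and prints a short interpretation):
`01_reactive_round.py` (reflex-only embodied rounds), `03_condition_grid.py`
(the 2×2 ballistic/dynamic × low/high design), `04_payoff_sweep.py`
(reliance on deliberate choices vs. payoff ratio from 1:1 to 32:1),
`05_metrics_from_csv.py` (round-log CSV round-trip).

A thin CLI wraps the same drivers:

```
crl-exes run --mode dynamic --payoff high --dyads 50 --seed 1 --out out/
crl-exes ablate --which all --payoff both --dyads 50 --out out/
crl-exes sweep --ratios 1,2,4,8,16,32 --dyads 50 --out out/
crl-exes metrics --log out/rounds_dynamic-high.csv
crl-exes report --in out/
```

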