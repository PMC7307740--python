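# Model and methods

This note documents the simulator's model, its default constants and the
reasoning behind the genuinely open design choices. Nothing here reports an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The game

Battle of the Exes is a repeated anti-coordination game for two players.
Each round offers a high reward `a` and a low reward `b` (`a >= b > 0`;
presets: high stakes 4/1, low stakes 2/1). If the players end up at
different spots each earns its spot's payoff; if they contest the same spot
both earn 0. A dyad plays 50 consecutive rounds in high-stakes conditions
and 60 in low-stakes ones, and the spot locations are re-randomized every
round, so any stable division of the rewards is a *convention* the pair has
to invent — turn-taking or dominance being the two obvious ones.

## Agent architecture

### Adaptive layer (once per round)

A tabular actor–critic temporal-difference learner over three states — the
previous round's outcome for that agent (*high*, *low*, *tie*) — and three
actions (*go-high*, *go-low*, *none*):

* TD error: `e = r + γ·V(s_t) − V(s_prev)` with discount `γ = 0.40`;
* critic update: `V(s_prev) += η·e`, learning rate `η = 0.15`;
* actor update: `C(a, s_prev) += δ·e`, rate `δ = 0.45`, with `C` clamped at
  0 from below;
* policy by Laplace's law of succession,
  `P(a|s) = (C(a,s)+1) / (Σ_a C(a,s) + 3)`, sampled each round.

`V` and `C` start at zero (uniform initial policy), the round-1 state is the
neutral *tie*, and exactly one update is applied per agent per round when
the reward is revealed. Agents learn independently — no parameter sharing
and no model of the partner. The learning constants are taken as given; the
sweep driver (`run_payoff_sweep`) is the generic utility for exploring
parameter ranges.

### Reactive layer (every integration step; dynamic mode only)

Braitenberg-style feedback control over six proximity sensors. For an
entity at surface distance `d` and bearing `β` relative to the heading, the
left/right activations are

    max(0, 1 − d / range) · max(0, cos(β ∓ halfangle)),

bounded in [0, 1]. Reward seeking uses crossed excitation (turn toward the
stronger side), collision avoidance the reverse (turn away); every active
behavior contributes its differential term on top of a single forward-speed
constant `f = 0.3`, and the summed wheel commands are clamped to [−1, 1].
The action chosen by the adaptive layer is locked in for the round as an
inhibition mask: *go-high* silences the low-spot attraction, *go-low* the
high-spot attraction, *none* leaves all reflexes on. Avoidance is never
inhibited. In the reactive-only ablation no action is taken at all (logged
as *none*, reliance 0) and nothing is learned; in the adaptive-only
ablation there is no body and rounds resolve exactly as ballistic play.

### Embodiment defaults (dynamic mode)

The continuous arena is configuration, not physics dogma; the defaults were
chosen to put the reflex-driven game into its interesting regime — both
agents drawn to the big reward, conflicts resolved or not by avoidance and
noise — rather than a degenerate one (each agent trivially claiming the
spot on its own side, which a naive symmetric layout produces).

| constant | default | meaning |
|---|---|---|
| arena | 20 × 20 units | square workspace |
| spot positions | (6, 14), (14, 14) | mirrored about the vertical midline; high/low allocation re-drawn per round |
| start poses | (8.5, 3), (11.5, 3), facing the spots | side by side, mirrored |
| spot visual radii | high 2, low 1 | the big spot is the high reward |
| `low_spot_gain` | 0.5 | small spot drives its sensor at half strength (smaller visual angle) |
| spot sensor range | arena diagonal (≈28.3) | spots salient from anywhere |
| agent sensor range | 3 | avoidance is a short-range reflex |
| `avoid_gain` | 1.0 | avoidance at unit gain |
| reach / tie radius | 1 / 3 | round ends at reach; tie if the trailing agent is inside the reached spot's circle |
| `dt`, speed scale, wheelbase | 0.1 s, 1 u/s, 1 u | differential drive, forward Euler |
| motor noise | σ = 0.05 per wheel per step | breaks the exact mirror symmetry of same-action rounds |
| `max_steps` | 1000 | timeout scores as a tie |

Surface-distance sensing plus the low-spot gain make the high reward the
shared primary attractor, so uncommitted pairs converge on it and tie about
half the time, with avoidance and noise deciding the rest — the
spontaneous-coordination regime. Without motor noise the arena's mirror
symmetry would make every same-action round an exact tie.

Scoring a decided round: the first agent to come within the reach radius of
a spot ends the round; if the other agent stands inside that same spot's
tie circle the round is a tie (both 0), otherwise the reacher earns its
spot's payoff and the other agent the other spot's payoff. This keeps every
decided round paying `a + b` collectively, makes efficiency identically
1 − tie fraction, and gives each agent a well-defined high/low state label.
Simultaneous arrivals and timeouts are ties.

## Metrics

* **Efficiency** — collective reward over `rounds · (a+b)`, in [0, 1].
* **Fairness** — `1 − |n_a − n_b| / (n_a + n_b)` where `n_i` counts the
  rounds agent `i` took the high reward; undefined (and excluded from
  aggregation, with a warning) for an all-tie dyad.
* **Stability** — mean surprisal of the 3-symbol outcome sequence
  (A-took-high / B-took-high / tie). Round `t`'s outcome probability is
  estimated from the preceding `min(window, t)` rounds with add-one
  smoothing (window 8), and surprisal is its negative logarithm. The
  default base is *e* (nats): under this estimator a fully random 3-symbol
  sequence costs ≈1.17 nats, a random binary one ≈0.83, a settled
  convention ≈0.3, which places the interesting dynamics on the scale the
  published values for this game occupy. Base 2 is one config flag away.
  Estimator choices (window, smoothing, base) shift absolute stability
  values; comparisons across conditions are the robust quantity.
* **Reliance on the adaptive layer** — fraction of agent-rounds with a
  committed action (not *none*); 2/3 under a uniform policy.
* **Convention classifier** (reporting convenience, not part of the game):
  over the last 20 non-tie rounds, *dominance* if one agent took the high
  reward ≥90% of the time, *turn-taking* if the winner alternates in ≥90%
  of consecutive pairs, else *none*; fewer than 4 decided rounds → *none*.

## Experiment drivers and statistics

`run_grid` (the 2×2 design), `run_ablations` (full / reactive-only /
adaptive-only × payoff) and `run_payoff_sweep` (ratios 1:1 … 32:1) all
derive one child seed per dyad from the master seed via
`numpy.random.SeedSequence`, and each dyad further splits into an
environment stream and one action-sampling stream per agent — so any single
dyad is reproducible in isolation and results are independent of execution
order. Outputs are plain CSV (one row per round; schema in
`crl_exes.engine.LOG_COLUMNS`) with a JSON config sidecar.

`run_stats` follows the usual decision rule for between-group comparisons:
Shapiro–Wilk per group, then one-way ANOVA with pairwise t-tests if all
groups pass, else Kruskal–Wallis with pairwise Mann–Whitney U. Groups under
3 dyads are skipped with a notice, and the report carries its true degrees
of freedom.

## Problem sizes

The acceptance script and the tier-1 acceptance tests run the full design:
50 dyads per condition, 50/60 rounds. Ordering and sweep checks in the test
suite replicate a reduced design (10 dyads per condition, 6 per sweep cell)
over five master seeds and compare seed-pooled means; unit and property
tests use purpose-built miniature configurations.

## What the simulation does and does not show

The synthetic world *is* the study system here — there is no external data
— but the embodiment is still a model of a model: circular agents, linear
falloff sensing, Gaussian motor noise, and a fixed round-start reset. Two
limitations matter when reading results:

* **Convention formation is weaker than the strongest published accounts of
  this architecture.** With actions *sampled* from the Laplace policy and
  the default learning constants, the critic's values saturate, TD errors
  shrink, and policies stabilize around 0.8–0.9 rather than hardening into
  near-deterministic conventions. Dyads show drifting dominance episodes
  and frequent contested rounds; full-model efficiency lands near 0.5
  rather than near 0.9, and the payoff-ratio sweep leaves reliance on the
  adaptive layer close to its 2/3 baseline instead of rising. A greedy
  (argmax) action rule produces hard conventions and much higher dynamic
  efficiency, but it is not the sampling rule this implementation commits
  to; the comparison is easy to reproduce by swapping `select_action`.
* **Reactive-only fairness is binomially limited.** With memoryless rounds
  and a mirror-symmetric arena, the winner of a decided reflex-only round
  is an independent fair coin, so per-dyad fairness concentrates near the
  binomial expectation (≈0.85 for ~25 decided rounds) and cannot fall to
  substantially lower values without some within-dyad asymmetry persisting
  across rounds, which this implementation deliberately does not have.

Numerical details worth knowing: wheel commands are clamped to [−1, 1]
after noise injection; headings are wrapped to (−π, π]; positions are
clamped so bodies stay inside the arena; TD errors are not clipped (only
the actor counts' lower bound applies); and policy columns are re-derived
from `C` after every update, so the Laplace normalization is an invariant,
not a convention.
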