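"""Game engine: dyads of agents playing repeated rounds of Battle of the Exes.

Battle of the Exes is an anti-coordination game: two reward spots pay ``a``
(high) and ``b`` (low) with ``a >= b > 0``; if both players contest the same
spot neither earns anything.  A dyad plays a fixed number of consecutive
rounds in one of two modes:

* **ballistic** — each round is a one-shot discrete choice resolved as the
  matrix game; only the adaptive layer acts.
* **dynamic** — each round is played out in the continuous arena, the full
  architecture steering the body until a spot is reached; the adaptive
  layer's action merely biases the reflexes through the inhibition mask.

Ablations: ``reactive_only`` runs dynamic rounds with the adaptive layer cut
(no action, no learning, every reflex active); ``adaptive_only`` keeps the
learner but removes the body, which makes its rounds identical to ballistic
play.

All randomness flows from one integer seed per dyad, split into independent
streams for the environment (spot allocation, motor noise, coin flips) and
for each agent's action sampling, so any dyad is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .arena import (
    AgentPose,
    ArenaConfig,
    check_round_end,
    read_sensors,
    step_kinematics,
)
from .adaptive import ActorCritic, LearningConfig, inhibition_for
from .reactive import FULL_MASK, ReactiveConfig, clamp_command, combine_behaviors

__all__ = [
    "PayoffScheme",
    "Condition",
    "RoundOutcome",
    "DyadLog",
    "PRESET_PAYOFFS",
    "SWEEP_PAYOFFS",
    "make_condition",
    "play_round_ballistic",
    "play_round_dynamic",
    "play_dyad",
    "LOG_COLUMNS",
    "logs_to_frame",
    "logs_from_frame",
    "write_log_csv",
    "read_log_csv",
]

MODES = ("ballistic", "dynamic")
ABLATIONS = ("full", "reactive_only", "adaptive_only")


@dataclass(frozen=True)
class PayoffScheme:
    """High/low spot payoffs; a tie always pays 0 to both."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError("payoffs must satisfy a >= b > 0")

    @property
    def name(self) -> str:
        if (self.a, self.b) == (4, 1):
            return "high"
        if (self.a, self.b) == (2, 1):
            return "low"
        return f"{self.a:g}-{self.b:g}"


PRESET_PAYOFFS = {"low": PayoffScheme(2, 1), "high": PayoffScheme(4, 1)}
#: payoff ladder for the reliance sweep, ordered by a/b ratio
SWEEP_PAYOFFS = tuple(PayoffScheme(a, 1) for a in (1, 2, 4, 8, 16, 32))
DEFAULT_ROUNDS = {"low": 60, "high": 50}


@dataclass(frozen=True)
class Condition:
    """One cell of the experimental design."""

    mode: str
    payoff: PayoffScheme
    rounds: int
    ablation: str = "full"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        if self.ablation != "full" and self.mode != "dynamic":
            raise ValueError("ablations are defined for the dynamic mode")

    @property
    def label(self) -> str:
        base = f"{self.mode}-{self.payoff.name}"
        return base if self.ablation == "full" else f"{base}-{self.ablation}"


def make_condition(
    mode: str,
    payoff: str | PayoffScheme = "high",
    rounds: Optional[int] = None,
    ablation: str = "full",
) -> Condition:
    """Build a condition, defaulting rounds to 50 (high) or 60 (low)."""
    if isinstance(payoff, str):
        payoff = PRESET_PAYOFFS[payoff]
    if rounds is None:
        rounds = DEFAULT_ROUNDS.get(payoff.name, 50)
    return Condition(mode, payoff, rounds, ablation)


@dataclass(frozen=True)
class RoundOutcome:
    """Record of one round, symmetric in the two agents a and b."""

    round_index: int
    action_a: str
    action_b: str
    state_a: str
    state_b: str
    reward_a: float
    reward_b: float
    tie: bool
    steps: int
    none_a: bool
    none_b: bool


@dataclass
class DyadLog:
    """Ordered round outcomes of one dyad in one condition under one seed."""

    dyad_id: int
    condition: Condition
    seed: int
    outcomes: List[RoundOutcome] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.outcomes)


def _spot_choice(action: str, rng: np.random.Generator) -> str:
    """Resolve an action to a spot; *none* flips a fair coin."""
    if action == "go_high":
        return "high"
    if action == "go_low":
        return "low"
    return "high" if rng.integers(2) == 0 else "low"


def _outcome(
    round_index: int,
    actions: Tuple[str, str],
    labels: Tuple[str, str],
    payoff: PayoffScheme,
    steps: int,
) -> RoundOutcome:
    tie = labels == ("tie", "tie")
    reward = {"high": payoff.a, "low": payoff.b, "tie": 0.0}
    return RoundOutcome(
        round_index,
        actions[0],
        actions[1],
        labels[0],
        labels[1],
        reward[labels[0]],
        reward[labels[1]],
        tie,
        steps,
        actions[0] == "none",
        actions[1] == "none",
    )


def play_round_ballistic(
    agent_a: ActorCritic,
    agent_b: ActorCritic,
    payoff: PayoffScheme,
    rng: np.random.Generator,
    rng_a: Optional[np.random.Generator] = None,
    rng_b: Optional[np.random.Generator] = None,
    round_index: int = 0,
) -> RoundOutcome:
    """One round resolved as the discrete matrix game.

    Each agent samples an action from its policy; *go_high*/*go_low* commit
    to the corresponding spot and *none* picks one uniformly at random.
    Identical spot choices tie (both earn 0); different choices pay each
    agent its spot's reward.  No learning happens here.
    """
    action_a = agent_a.choose(rng_a if rng_a is not None else rng)
    action_b = agent_b.choose(rng_b if rng_b is not None else rng)
    spot_a = _spot_choice(action_a, rng)
    spot_b = _spot_choice(action_b, rng)
    labels = ("tie", "tie") if spot_a == spot_b else (spot_a, spot_b)
    return _outcome(round_index, (action_a, action_b), labels, payoff, 0)


def play_round_dynamic(
    agent_a: Optional[ActorCritic],
    agent_b: Optional[ActorCritic],
    payoff: PayoffScheme,
    cfg: ArenaConfig,
    rcfg: ReactiveConfig,
    rng: np.random.Generator,
    rng_a: Optional[np.random.Generator] = None,
    rng_b: Optional[np.random.Generator] = None,
    round_index: int = 0,
    forced_actions: Optional[Tuple[str, str]] = None,
) -> RoundOutcome:
    """One embodied round in the continuous arena.

    The high reward is allocated to one of the two spot positions at random,
    each agent fixes its inhibition mask from its sampled action (or from
    ``forced_actions``; the reactive-only ablation forces *none* for both),
    and the sense-combine-step loop runs for both agents synchronously until
    one reaches a spot or the step cap is hit.

    Scoring: if, the moment the first agent reaches a spot, the other agent
    stands inside that same spot's tie circle, the round is a tie and both
    earn 0.  Otherwise the reacher earns its spot's payoff and the other
    agent the other spot's payoff, so every decided round pays out exactly
    ``a + b``.  Simultaneous arrivals and timeouts are ties.
    """
    if forced_actions is not None:
        action_a, action_b = forced_actions
    else:
        action_a = agent_a.choose(rng_a if rng_a is not None else rng)
        action_b = agent_b.choose(rng_b if rng_b is not None else rng)
    mask_a = inhibition_for(action_a)
    mask_b = inhibition_for(action_b)

    positions = cfg.spot_positions
    alloc = int(rng.integers(2))
    spot_high = positions[alloc]
    spot_low = positions[1 - alloc]

    pa = AgentPose(*cfg.agent_start_poses[0])
    pb = AgentPose(*cfg.agent_start_poses[1])

    steps = 0
    noise = None
    noise_i = 0
    labels: Tuple[str, str] = ("tie", "tie")
    while True:
        steps += 1
        if noise is None or noise_i >= len(noise):
            noise = rng.standard_normal((128, 4)) * cfg.motor_noise
            noise_i = 0
        nz = noise[noise_i]
        noise_i += 1

        sa = read_sensors(pa, pb, spot_high, spot_low, cfg)
        sb = read_sensors(pb, pa, spot_high, spot_low, cfg)
        ca = combine_behaviors(sa, mask_a, rcfg)
        cb = combine_behaviors(sb, mask_b, rcfg)
        ca = clamp_command(ca.m_left + nz[0], ca.m_right + nz[1], rcfg)
        cb = clamp_command(cb.m_left + nz[2], cb.m_right + nz[3], rcfg)
        pa = step_kinematics(pa, ca, cfg)
        pb = step_kinematics(pb, cb, cfg)

        verdict = check_round_end(pa, pb, spot_high, spot_low, cfg, steps)
        if verdict.kind == "none":
            continue
        if verdict.kind == "timeout" or len(verdict.reached) == 2:
            labels = ("tie", "tie")
        else:
            (idx, spot_label), = verdict.reached
            spot = spot_high if spot_label == "high" else spot_low
            other_pose = pb if idx == 0 else pa
            d_other = np.hypot(other_pose.x - spot[0], other_pose.y - spot[1])
            if d_other <= cfg.tie_radius:
                labels = ("tie", "tie")
            else:
                other_label = "low" if spot_label == "high" else "high"
                labels = (
                    (spot_label, other_label) if idx == 0 else (other_label, spot_label)
                )
        break
    return _outcome(round_index, (action_a, action_b), labels, payoff, steps)


def play_dyad(
    condition: Condition,
    seed: int,
    dyad_id: int = 0,
    arena_cfg: Optional[ArenaConfig] = None,
    reactive_cfg: Optional[ReactiveConfig] = None,
    learning_cfg: Optional[LearningConfig] = None,
    return_agents: bool = False,
):
    """Play all rounds of one dyad, updating both learners after each round.

    Fresh learners are created for the dyad; after every round each agent
    applies one TD update from its own ``(s_prev, a, r, s)`` tuple, and the
    round's outcome label becomes its next ``s_prev``.  The whole log is a
    pure function of ``(condition, seed)``.  With ``return_agents`` the
    final learners come back alongside the log so their policy and value
    tables can be dumped for inspection (``ActorCritic.to_dict``).
    """
    ss = np.random.SeedSequence(seed)
    env_ss, a_ss, b_ss = ss.spawn(3)
    rng = np.random.default_rng(env_ss)
    rng_a = np.random.default_rng(a_ss)
    rng_b = np.random.default_rng(b_ss)

    arena_cfg = arena_cfg or ArenaConfig()
    reactive_cfg = reactive_cfg or ReactiveConfig()
    learning = condition.ablation != "reactive_only"
    agent_a = ActorCritic(learning_cfg) if learning else None
    agent_b = ActorCritic(learning_cfg) if learning else None

    log = DyadLog(dyad_id, condition, seed)
    for r in range(condition.rounds):
        if condition.mode == "ballistic" or condition.ablation == "adaptive_only":
            out = play_round_ballistic(
                agent_a, agent_b, condition.payoff, rng, rng_a, rng_b, r
            )
        elif condition.ablation == "reactive_only":
            out = play_round_dynamic(
                None,
                None,
                condition.payoff,
                arena_cfg,
                reactive_cfg,
                rng,
                round_index=r,
                forced_actions=("none", "none"),
            )
        else:
            out = play_round_dynamic(
                agent_a,
                agent_b,
                condition.payoff,
                arena_cfg,
                reactive_cfg,
                rng,
                rng_a,
                rng_b,
                r,
            )
        if learning:
            agent_a.learn(out.action_a, out.reward_a, out.state_a)
            agent_b.learn(out.action_b, out.reward_b, out.state_b)
        log.outcomes.append(out)
    if return_agents:
        return log, (agent_a, agent_b)
    return log


# ---------------------------------------------------------------------------
# Tabular log I/O

LOG_COLUMNS = [
    "dyad_id",
    "condition",
    "mode",
    "payoff_a",
    "payoff_b",
    "ablation",
    "seed",
    "round",
    "action_a",
    "action_b",
    "state_a",
    "state_b",
    "reward_a",
    "reward_b",
    "tie",
    "steps",
    "none_a",
    "none_b",
]


def logs_to_frame(logs: Sequence[DyadLog]) -> pd.DataFrame:
    """Flatten dyad logs into one row per round with the canonical columns."""
    rows = []
    for log in logs:
        c = log.condition
        for o in log.outcomes:
            rows.append(
                (
                    log.dyad_id,
                    c.label,
                    c.mode,
                    c.payoff.a,
                    c.payoff.b,
                    c.ablation,
                    log.seed,
                    o.round_index,
                    o.action_a,
                    o.action_b,
                    o.state_a,
                    o.state_b,
                    o.reward_a,
                    o.reward_b,
                    o.tie,
                    o.steps,
                    o.none_a,
                    o.none_b,
                )
            )
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def logs_from_frame(df: pd.DataFrame) -> List[DyadLog]:
    """Rebuild DyadLog objects from a round-log table (inverse of logs_to_frame)."""
    logs = []
    for (dyad_id, label), g in df.groupby(["dyad_id", "condition"], sort=False):
        g = g.sort_values("round")
        first = g.iloc[0]
        cond = Condition(
            str(first["mode"]),
            PayoffScheme(float(first["payoff_a"]), float(first["payoff_b"])),
            len(g),
            str(first["ablation"]),
        )
        outcomes = [
            RoundOutcome(
                int(r["round"]),
                str(r["action_a"]),
                str(r["action_b"]),
                str(r["state_a"]),
                str(r["state_b"]),
                float(r["reward_a"]),
                float(r["reward_b"]),
                bool(r["tie"]),
                int(r["steps"]),
                bool(r["none_a"]),
                bool(r["none_b"]),
            )
            for _, r in g.iterrows()
        ]
        logs.append(DyadLog(int(dyad_id), cond, int(first["seed"]), outcomes))
    return logs


def write_log_csv(logs: Sequence[DyadLog], path: str | Path, config: dict | None = None) -> Path:
    """Write logs as CSV; an optional config dict goes to a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    logs_to_frame(logs).to_csv(path, index=False)
    if config is not None:
        sidecar = path.with_suffix(".config.json")
        sidecar.write_text(json.dumps(config, indent=2, sort_keys=True, default=str))
    return path


def read_log_csv(path: str | Path) -> pd.DataFrame:
    """Read a round-log CSV, checking the canonical schema."""
    df = pd.read_csv(path)
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"round log is missing columns: {missing}")
    return df[LOG_COLUMNS]
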