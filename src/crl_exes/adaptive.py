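"""Adaptive layer: tabular actor-critic temporal-difference learning.

Once per round the adaptive layer observes the previous round's outcome
(one of three states: *high*, *low*, *tie*), samples one of three actions
(*go_high*, *go_low*, *none*) from its policy, and after the round updates
both a critic (state values ``V``) and an actor (a count matrix ``C`` mapped
to probabilities ``P`` by Laplace's law of succession) from the TD error

    e = r + gamma * V(s_t) - V(s_prev).

The chosen action is translated into an inhibition mask for the reactive
layer: committing to one spot switches off the attraction to the other,
while *none* leaves all reflexes active.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reactive import InhibitionMask

__all__ = [
    "STATES",
    "ACTIONS",
    "LearningConfig",
    "PolicyTable",
    "ValueTable",
    "ActorCritic",
    "select_action",
    "td_error",
    "update_critic",
    "update_actor",
    "inhibition_for",
]

STATES = ("high", "low", "tie")
ACTIONS = ("go_high", "go_low", "none")
STATE_INDEX = {s: i for i, s in enumerate(STATES)}
ACTION_INDEX = {a: i for i, a in enumerate(ACTIONS)}

_MASKS = {
    "go_high": InhibitionMask(high_seek_active=True, low_seek_active=False),
    "go_low": InhibitionMask(high_seek_active=False, low_seek_active=True),
    "none": InhibitionMask(high_seek_active=True, low_seek_active=True),
}


@dataclass(frozen=True)
class LearningConfig:
    """TD-learning constants.

    gamma : discount factor on future state value (default 0.40)
    eta   : critic learning rate (default 0.15)
    delta : actor learning rate (default 0.45)
    k     : number of actions, the Laplace pseudocount total (3)
    """

    gamma: float = 0.40
    eta: float = 0.15
    delta: float = 0.45
    k: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.eta < 0 or self.delta < 0:
            raise ValueError("learning rates must be non-negative")


class PolicyTable:
    """Actor state: non-negative counts ``C`` and the probabilities ``P``.

    Both are 3x3 arrays indexed ``[action, state]``.  ``P`` is always the
    Laplace-smoothed image of ``C``:

        P(a | s) = (C[a, s] + 1) / (sum_a' C[a', s] + k)

    so a fresh (all-zero) table is exactly uniform and no probability is
    ever zero.
    """

    __slots__ = ("C", "P", "k")

    def __init__(self, k: int = 3):
        self.k = k
        self.C = np.zeros((len(ACTIONS), len(STATES)))
        self.P = np.full((len(ACTIONS), len(STATES)), 1.0 / len(ACTIONS))

    def refresh(self, state_idx: int | None = None) -> None:
        """Recompute ``P`` from ``C`` (one column, or all when None)."""
        cols = slice(None) if state_idx is None else state_idx
        c = self.C[:, cols]
        self.P[:, cols] = (c + 1.0) / (c.sum(axis=0) + self.k)

    def probs(self, state: str) -> np.ndarray:
        return self.P[:, STATE_INDEX[state]]


class ValueTable:
    """Critic state: one expected-return estimate per state, initialised to 0."""

    __slots__ = ("V",)

    def __init__(self):
        self.V = np.zeros(len(STATES))

    def __getitem__(self, state: str) -> float:
        return float(self.V[STATE_INDEX[state]])


def select_action(policy: PolicyTable, state: str, rng: np.random.Generator) -> str:
    """Sample an action from ``P(. | state)`` using the supplied stream."""
    p = policy.probs(state)
    total = p.sum()
    if not np.isclose(total, 1.0):
        raise RuntimeError(f"policy column for state {state!r} sums to {total}")
    return ACTIONS[int(rng.choice(len(ACTIONS), p=p / total))]


def td_error(
    r_t: float, values: ValueTable, s_t: str, s_prev: str, cfg: LearningConfig
) -> float:
    """Temporal-difference error e = r + gamma * V(s_t) - V(s_prev)."""
    return r_t + cfg.gamma * values[s_t] - values[s_prev]


def update_critic(
    values: ValueTable, s_prev: str, e: float, cfg: LearningConfig
) -> ValueTable:
    """Move V(s_prev) by eta * e; all other entries untouched."""
    values.V[STATE_INDEX[s_prev]] += cfg.eta * e
    return values


def update_actor(
    policy: PolicyTable, a_t: str, s_prev: str, e: float, cfg: LearningConfig
) -> PolicyTable:
    """Integrate the TD error into C(a_t, s_prev) and refresh probabilities.

    The count is kept to its lower bound of 0, so a string of negative
    errors drives the column back toward the uniform distribution rather
    than producing negative mass.
    """
    ai, si = ACTION_INDEX[a_t], STATE_INDEX[s_prev]
    policy.C[ai, si] = max(0.0, policy.C[ai, si] + cfg.delta * e)
    policy.refresh(si)
    return policy


def inhibition_for(action: str) -> InhibitionMask:
    """Map the chosen action to the reactive-layer inhibition mask.

    Committing to one spot inhibits attraction to the other; *none* leaves
    everything active.  Collision avoidance is never inhibited.
    """
    return _MASKS[action]


class ActorCritic:
    """One agent's adaptive layer bundled with its running state.

    Tracks ``state`` (the previous round's outcome label, starting at the
    neutral ``"tie"``), samples actions, and applies one full TD update per
    round when the reward is revealed.
    """

    def __init__(self, cfg: LearningConfig | None = None):
        self.cfg = cfg or LearningConfig()
        self.policy = PolicyTable(self.cfg.k)
        self.values = ValueTable()
        self.state = "tie"

    def choose(self, rng: np.random.Generator) -> str:
        return select_action(self.policy, self.state, rng)

    def to_dict(self) -> dict:
        """JSON-serializable snapshot of the learner for inspection dumps."""
        return {
            "states": list(STATES),
            "actions": list(ACTIONS),
            "C": self.policy.C.tolist(),
            "P": self.policy.P.tolist(),
            "V": self.values.V.tolist(),
            "state": self.state,
        }

    def learn(self, action: str, reward: float, new_state: str) -> float:
        """One round's TD update from (s_prev, a, r, s_t); returns the error."""
        e = td_error(reward, self.values, new_state, self.state, self.cfg)
        update_critic(self.values, self.state, e, self.cfg)
        update_actor(self.policy, action, self.state, e, self.cfg)
        self.state = new_state
        return e
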