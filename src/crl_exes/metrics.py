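"""Coordination metrics over dyad round logs.

Three measures summarise how well a dyad solves the repeated
anti-coordination problem:

* **efficiency** — collective reward earned divided by the maximum
  collectively attainable (``rounds * (a + b)``); under the scoring rule it
  equals the fraction of rounds that did not tie.
* **fairness** — how evenly the high reward was split:
  ``1 - |n_a - n_b| / (n_a + n_b)`` over the non-tie rounds.
* **stability** — mean *surprisal* of the round outcomes, i.e. the negative
  log-probability of each round's outcome under an empirical predictor fed
  by the recent past.  Low surprisal means the dyad settled into a
  predictable convention.

Additionally, *reliance on the adaptive layer* is the fraction of
agent-rounds in which a spot-choice action (not *none*) was taken, and a
simple classifier labels the end-of-game regime as turn-taking, dominance
or neither.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import DyadLog

__all__ = [
    "SurprisalConfig",
    "UndefinedMetricError",
    "MetricsReport",
    "outcome_symbols",
    "efficiency",
    "fairness",
    "stability",
    "reliance_adaptive",
    "classify_convention",
    "dyad_metrics",
    "summarize_condition",
]

SYMBOLS = ("a_high", "b_high", "tie")


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value on the given log."""


@dataclass(frozen=True)
class SurprisalConfig:
    """Free parameters of the surprisal estimator.

    ``window`` rounds of history feed the outcome-probability estimate;
    add-one (Laplace) ``smoothing`` over the 3-symbol alphabet keeps every
    probability positive.  ``log_base`` defaults to Euler's number, reporting
    surprisal in nats; use 2 for bits.
    """

    window: int = 8
    smoothing: bool = True
    log_base: float = 2.718281828459045

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.log_base <= 1:
            raise ValueError("log_base must exceed 1")

    @property
    def max_surprisal(self) -> float:
        """Upper bound of one round's surprisal under add-one smoothing."""
        return math.log(self.window + len(SYMBOLS), self.log_base)


class SurprisalResult(NamedTuple):
    mean: float
    series: np.ndarray


def outcome_symbols(log: DyadLog) -> List[str]:
    """Per-round outcome symbol: which agent took the high reward, or tie."""
    out = []
    for o in log.outcomes:
        if o.state_a == "high":
            out.append("a_high")
        elif o.state_b == "high":
            out.append("b_high")
        else:
            out.append("tie")
    return out


def _require_rounds(log: DyadLog, metric: str) -> None:
    if not log.outcomes:
        raise UndefinedMetricError(f"{metric} is undefined on an empty log")


def efficiency(log: DyadLog) -> float:
    """Collective reward earned over the maximum attainable, in [0, 1]."""
    _require_rounds(log, "efficiency")
    p = log.condition.payoff
    total = sum(o.reward_a + o.reward_b for o in log.outcomes)
    return total / (len(log.outcomes) * (p.a + p.b))


def fairness(log: DyadLog) -> float:
    """Balance of high-reward acquisitions: 1 - |n_a - n_b| / (n_a + n_b).

    Computed over non-tie rounds only; raises ``UndefinedMetricError`` when
    every round tied.
    """
    _require_rounds(log, "fairness")
    n_a = sum(1 for o in log.outcomes if o.state_a == "high")
    n_b = sum(1 for o in log.outcomes if o.state_b == "high")
    if n_a + n_b == 0:
        raise UndefinedMetricError("fairness is undefined on an all-tie log")
    return 1.0 - abs(n_a - n_b) / (n_a + n_b)


def stability(log: DyadLog, cfg: Optional[SurprisalConfig] = None) -> SurprisalResult:
    """Mean and per-round surprisal of the outcome sequence.

    For round ``t`` the probability of its outcome is estimated from the
    preceding ``min(window, t)`` rounds; with add-one smoothing an empty
    history yields the uniform 1/3, so the first round always costs
    ``ln 3 = 1.099`` nats (1.585 bits with ``log_base=2``).  Lower mean
    surprisal = a more stable convention.
    """
    _require_rounds(log, "stability")
    cfg = cfg or SurprisalConfig()
    symbols = outcome_symbols(log)
    idx = {s: i for i, s in enumerate(SYMBOLS)}
    counts = np.zeros(len(SYMBOLS))
    series = np.empty(len(symbols))
    log_base = math.log(cfg.log_base)
    for t, sym in enumerate(symbols):
        m = counts.sum()
        c = counts[idx[sym]]
        if cfg.smoothing:
            p = (c + 1.0) / (m + len(SYMBOLS))
        else:
            p = c / m if m > 0 else 1.0 / len(SYMBOLS)
        series[t] = math.inf if p == 0 else -math.log(p) / log_base
        counts[idx[sym]] += 1
        if t >= cfg.window:
            counts[idx[symbols[t - cfg.window]]] -= 1
    return SurprisalResult(float(series.mean()), series)


def reliance_adaptive(log: DyadLog) -> float:
    """Fraction of agent-rounds with a spot-choice action (not *none*)."""
    _require_rounds(log, "reliance_adaptive")
    chosen = sum((not o.none_a) + (not o.none_b) for o in log.outcomes)
    return chosen / (2 * len(log.outcomes))


def classify_convention(log: DyadLog, tail: int = 20) -> str:
    """Label the dyad's end-of-game regime.

    Over the last ``tail`` non-tie rounds: *dominance* if one agent took the
    high reward in at least 90% of them; *turn_taking* if the winner strictly
    alternates in at least 90% of consecutive pairs; otherwise (or with
    fewer than 4 non-tie tail rounds) *none*.  The thresholds are reporting
    conveniences, not part of the game definition.
    """
    if tail > len(log.outcomes):
        raise ValueError("tail exceeds the number of rounds")
    winners = [s for s in outcome_symbols(log) if s != "tie"][-tail:]
    if len(winners) < 4:
        return "none"
    share_a = winners.count("a_high") / len(winners)
    if max(share_a, 1.0 - share_a) >= 0.9:
        return "dominance"
    alternations = sum(
        1 for w, nxt in zip(winners, winners[1:]) if w != nxt
    )
    if alternations / (len(winners) - 1) >= 0.9:
        return "turn_taking"
    return "none"


def dyad_metrics(
    log: DyadLog,
    surprisal_cfg: Optional[SurprisalConfig] = None,
    tail: int = 20,
) -> dict:
    """All per-dyad metrics as one flat record (fairness NaN when undefined)."""
    try:
        fair = fairness(log)
    except UndefinedMetricError:
        warnings.warn(
            f"dyad {log.dyad_id}: all rounds tied, fairness undefined",
            stacklevel=2,
        )
        fair = math.nan
    return {
        "dyad_id": log.dyad_id,
        "condition": log.condition.label,
        "seed": log.seed,
        "efficiency": efficiency(log),
        "fairness": fair,
        "stability": stability(log, surprisal_cfg).mean,
        "reliance_adaptive": reliance_adaptive(log),
        "convention": classify_convention(log, min(tail, len(log.outcomes))),
    }


@dataclass
class MetricsReport:
    """Per-dyad metric table plus per-condition aggregates.

    ``summary`` maps each numeric metric to mean, standard error across
    dyads, and the number of dyads it was computed from (fairness may use
    fewer when all-tie dyads are excluded); ``conventions`` counts dyads per
    regime label.
    """

    condition: str
    per_dyad: pd.DataFrame
    summary: dict
    conventions: dict


def summarize_condition(
    logs: Sequence[DyadLog],
    surprisal_cfg: Optional[SurprisalConfig] = None,
    tail: int = 20,
) -> MetricsReport:
    """Aggregate dyad metrics into a condition-level report (mean +- SE)."""
    if not logs:
        raise UndefinedMetricError("cannot summarize an empty set of dyad logs")
    per_dyad = pd.DataFrame([dyad_metrics(l, surprisal_cfg, tail) for l in logs])
    summary = {}
    for metric in ("efficiency", "fairness", "stability", "reliance_adaptive"):
        vals = per_dyad[metric].dropna().to_numpy()
        n = len(vals)
        summary[metric] = {
            "mean": float(vals.mean()) if n else math.nan,
            "sem": float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan,
            "n": n,
        }
    conventions = per_dyad["convention"].value_counts().to_dict()
    return MetricsReport(logs[0].condition.label, per_dyad, summary, conventions)
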