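"""End-to-end experiment drivers: the 2x2 grid, layer ablations and the
payoff sweep.

Every driver is deterministic under its master seed: the seed is stretched
into one child seed per dyad through ``numpy.random.SeedSequence``, so each
dyad is reproducible in isolation and results do not depend on execution
order.  Drivers return in-memory results and, when an output directory is
given, persist the round logs (CSV + JSON config sidecar), the per-dyad
metric tables and the per-condition summaries.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .arena import ArenaConfig
from .adaptive import LearningConfig
from .engine import (
    Condition,
    DyadLog,
    PayoffScheme,
    SWEEP_PAYOFFS,
    make_condition,
    play_dyad,
    write_log_csv,
)
from .metrics import MetricsReport, SurprisalConfig, reliance_adaptive, summarize_condition
from .reactive import ReactiveConfig
from .stats import StatsSummary, run_stats

__all__ = [
    "ExperimentPlan",
    "dyad_seeds",
    "run_condition",
    "run_grid",
    "run_ablations",
    "run_payoff_sweep",
    "run_stats",
    "default_grid_plan",
]

DEFAULT_DYADS = 50


@dataclass
class ExperimentPlan:
    """A named set of conditions to run with shared dyad count and seed."""

    conditions: Dict[str, Condition]
    dyads: int = DEFAULT_DYADS
    seed: int = 0
    outdir: Optional[Path] = None
    arena_cfg: ArenaConfig = field(default_factory=ArenaConfig)
    reactive_cfg: ReactiveConfig = field(default_factory=ReactiveConfig)
    learning_cfg: LearningConfig = field(default_factory=LearningConfig)
    surprisal_cfg: SurprisalConfig = field(default_factory=SurprisalConfig)

    def __post_init__(self) -> None:
        if self.dyads < 1:
            raise ValueError("need at least one dyad per condition")
        if len(set(self.conditions.values())) != len(self.conditions):
            raise ValueError("plan conditions must be distinct")
        if self.outdir is not None:
            self.outdir = Path(self.outdir)


def default_grid_plan(seed: int = 0, dyads: int = DEFAULT_DYADS, outdir=None) -> ExperimentPlan:
    """The 2x2 design: {ballistic, dynamic} x {low, high} payoffs."""
    conds = {
        f"{mode}-{payoff}": make_condition(mode, payoff)
        for mode in ("ballistic", "dynamic")
        for payoff in ("low", "high")
    }
    return ExperimentPlan(conds, dyads=dyads, seed=seed, outdir=outdir)


def dyad_seeds(master_seed: int, n: int, stream: int = 0) -> List[int]:
    """Derive ``n`` independent per-dyad seeds (< 2**31) from a master seed.

    ``stream`` separates condition families so different experiments under
    one master seed do not share dyad seeds.
    """
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(stream,))
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def run_condition(
    condition: Condition,
    dyads: int,
    master_seed: int,
    stream: int = 0,
    arena_cfg: Optional[ArenaConfig] = None,
    reactive_cfg: Optional[ReactiveConfig] = None,
    learning_cfg: Optional[LearningConfig] = None,
) -> List[DyadLog]:
    """Simulate all dyads of one condition; raises with the dyad seed on failure."""
    logs = []
    for dyad_id, seed in enumerate(dyad_seeds(master_seed, dyads, stream)):
        try:
            logs.append(
                play_dyad(
                    condition,
                    seed,
                    dyad_id=dyad_id,
                    arena_cfg=arena_cfg,
                    reactive_cfg=reactive_cfg,
                    learning_cfg=learning_cfg,
                )
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"dyad {dyad_id} (seed {seed}) of {condition.label} failed"
            ) from exc
    return logs


def _plan_config(plan: ExperimentPlan) -> dict:
    return {
        "dyads": plan.dyads,
        "seed": plan.seed,
        "conditions": {k: dataclasses.asdict(c) for k, c in plan.conditions.items()},
        "arena": dataclasses.asdict(plan.arena_cfg),
        "reactive": dataclasses.asdict(plan.reactive_cfg),
        "learning": dataclasses.asdict(plan.learning_cfg),
        "surprisal": dataclasses.asdict(plan.surprisal_cfg),
    }


def _persist(plan: ExperimentPlan, name: str, logs, report: MetricsReport) -> None:
    if plan.outdir is None:
        return
    plan.outdir.mkdir(parents=True, exist_ok=True)
    write_log_csv(logs, plan.outdir / f"rounds_{name}.csv", config=_plan_config(plan))
    report.per_dyad.to_csv(plan.outdir / f"metrics_{name}.csv", index=False)
    payload = {"condition": report.condition, "summary": report.summary,
               "conventions": report.conventions}
    (plan.outdir / f"summary_{name}.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True)
    )


def run_grid(plan: ExperimentPlan) -> Dict[str, MetricsReport]:
    """Run every condition of the plan and aggregate metrics per condition."""
    reports = {}
    for stream, (name, cond) in enumerate(sorted(plan.conditions.items())):
        if cond.rounds == 0:
            warnings.warn(f"condition {name} has 0 rounds; metrics are empty")
            reports[name] = MetricsReport(cond.label, pd.DataFrame(), {}, {})
            continue
        logs = run_condition(
            cond, plan.dyads, plan.seed, stream,
            plan.arena_cfg, plan.reactive_cfg, plan.learning_cfg,
        )
        report = summarize_condition(logs, plan.surprisal_cfg)
        reports[name] = report
        _persist(plan, name, logs, report)
    return reports


def run_ablations(
    plan: Optional[ExperimentPlan] = None,
    seed: int = 0,
    dyads: int = DEFAULT_DYADS,
    outdir=None,
) -> Dict[str, MetricsReport]:
    """Run the ablation grid: {full, reactive_only, adaptive_only} x {low, high}.

    All cells run in dynamic mode (the ablations are defined against the
    embodied game; ``adaptive_only`` resolves rounds exactly as ballistic
    play does).
    """
    if plan is None:
        conds = {
            f"{ablation}-{payoff}": make_condition("dynamic", payoff, ablation=ablation)
            for ablation in ("full", "reactive_only", "adaptive_only")
            for payoff in ("low", "high")
        }
        plan = ExperimentPlan(conds, dyads=dyads, seed=seed, outdir=outdir)
    return run_grid(plan)


def run_payoff_sweep(
    payoffs: Sequence[PayoffScheme] = SWEEP_PAYOFFS,
    dyads: int = DEFAULT_DYADS,
    seed: int = 0,
    mode: str = "dynamic",
    rounds: int = 50,
    outdir=None,
) -> pd.DataFrame:
    """Mean reliance on the adaptive layer across a payoff ladder.

    Payoffs must be ordered by increasing a/b ratio.  Returns one row per
    payoff with mean, standard error and dyad count of the per-dyad
    reliance (fraction of non-*none* actions).
    """
    ratios = [p.a / p.b for p in payoffs]
    if any(r2 < r1 for r1, r2 in zip(ratios, ratios[1:])):
        raise ValueError("payoff list must be ordered by a/b ratio")
    rows = []
    for stream, payoff in enumerate(payoffs):
        cond = Condition(mode, payoff, rounds)
        logs = run_condition(cond, dyads, seed, stream=100 + stream)
        vals = np.array([reliance_adaptive(l) for l in logs])
        rows.append(
            {
                "payoff": payoff.name,
                "a": payoff.a,
                "b": payoff.b,
                "ratio": payoff.a / payoff.b,
                "reliance_mean": vals.mean(),
                "reliance_sem": vals.std(ddof=1) / np.sqrt(len(vals))
                if len(vals) > 1
                else np.nan,
                "n_dyads": len(vals),
            }
        )
    df = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "payoff_sweep.csv", index=False)
    return df
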