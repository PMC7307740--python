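"""Condition-comparison statistics for metric distributions across dyads.

The test family follows the usual decision rule for between-groups designs:
a Shapiro-Wilk normality screen per group; if every group passes, a one-way
ANOVA with pairwise independent-samples t-tests, otherwise a Kruskal-Wallis
H-test with pairwise Mann-Whitney U-tests.  Nothing here is novel — the
harness exists so condition comparisons ship in a machine-readable report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["StatsSummary", "compare_groups", "run_stats"]

MIN_GROUP = 3


@dataclass
class StatsSummary:
    """Machine-readable record of one metric's group comparison."""

    metric: str
    normal: bool
    normality: Dict[str, float]
    omnibus_test: str
    omnibus_stat: float
    omnibus_p: float
    pairwise_test: str
    pairwise: Dict[str, dict] = field(default_factory=dict)
    skipped: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "normal": self.normal,
            "normality_p": self.normality,
            "omnibus": {
                "test": self.omnibus_test,
                "stat": self.omnibus_stat,
                "p": self.omnibus_p,
            },
            "pairwise_test": self.pairwise_test,
            "pairwise": self.pairwise,
            "skipped": self.skipped,
        }


def compare_groups(
    groups: Dict[str, Sequence[float]], metric: str = "", alpha: float = 0.05
) -> StatsSummary:
    """Compare >= 2 groups of per-dyad metric values.

    Groups smaller than 3 dyads are dropped with a notice (recorded in
    ``skipped``); degenerate (zero-variance) groups force the rank-based
    family since Shapiro-Wilk is undefined on constants.
    """
    clean = {}
    skipped = []
    for name, vals in groups.items():
        arr = np.asarray([v for v in vals if np.isfinite(v)], dtype=float)
        if len(arr) < MIN_GROUP:
            skipped.append(name)
        else:
            clean[name] = arr
    if len(clean) < 2:
        raise ValueError("need at least two groups of >= 3 values")

    normality = {}
    normal = True
    for name, arr in clean.items():
        if np.ptp(arr) == 0:
            normality[name] = 0.0
            normal = False
            continue
        p = float(sps.shapiro(arr).pvalue)
        normality[name] = p
        normal &= p > alpha

    samples = list(clean.values())
    if normal:
        stat, p = sps.f_oneway(*samples)
        omnibus, pair_name = "anova", "t"
    else:
        try:
            stat, p = sps.kruskal(*samples)
        except ValueError:
            stat, p = 0.0, 1.0
        if np.isnan(p):  # all values identical across every group
            stat, p = 0.0, 1.0
        omnibus, pair_name = "kruskal", "mannwhitney"

    summary = StatsSummary(
        metric, normal, normality, omnibus, float(stat), float(p), pair_name, {}, skipped
    )
    for (na, va), (nb, vb) in combinations(clean.items(), 2):
        if normal:
            res = sps.ttest_ind(va, vb)
        else:
            if np.ptp(np.concatenate([va, vb])) == 0:
                summary.pairwise[f"{na} vs {nb}"] = {"stat": 0.0, "p": 1.0}
                continue
            res = sps.mannwhitneyu(va, vb, alternative="two-sided")
        summary.pairwise[f"{na} vs {nb}"] = {
            "stat": float(res.statistic),
            "p": float(res.pvalue),
        }
    return summary


def run_stats(
    reports: Dict[str, "object"],
    metrics: Sequence[str] = ("efficiency", "fairness", "stability"),
) -> Dict[str, StatsSummary]:
    """Compare conditions on each metric, given per-condition MetricsReports."""
    out = {}
    for metric in metrics:
        groups = {
            name: rep.per_dyad[metric].dropna().to_numpy()
            for name, rep in reports.items()
        }
        out[metric] = compare_groups(groups, metric)
    return out
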