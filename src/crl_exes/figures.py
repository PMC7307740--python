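"""Optional rendering of the standard result figures.

Everything here is data-first: each helper takes (or writes) the plain
table behind the plot, so analyses are testable without image comparison.
matplotlib is imported lazily and is only needed if a figure is rendered.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from .metrics import MetricsReport, SurprisalConfig, stability

__all__ = ["summary_table", "plot_condition_bars", "plot_surprisal_traces"]


def summary_table(reports: Dict[str, MetricsReport]) -> pd.DataFrame:
    """One row per condition with mean and standard error of each metric."""
    rows = []
    for name, rep in reports.items():
        row = {"condition": name}
        for metric, agg in rep.summary.items():
            row[f"{metric}_mean"] = agg["mean"]
            row[f"{metric}_sem"] = agg["sem"]
            row[f"{metric}_n"] = agg["n"]
        rows.append(row)
    return pd.DataFrame(rows)


def plot_condition_bars(
    reports: Dict[str, MetricsReport],
    metrics=("efficiency", "fairness", "stability"),
    path: Optional[Path] = None,
):
    """Bar chart of per-condition means with standard-error bars.

    Writes the underlying table next to the figure when ``path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = summary_table(reports)
    fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 3.2))
    for ax, metric in zip(axes, metrics):
        ax.bar(
            table["condition"],
            table[f"{metric}_mean"],
            yerr=table[f"{metric}_sem"],
            capsize=3,
            color="#4878a8",
        )
        ax.set_title(metric)
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    if path is not None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, dpi=150)
        table.to_csv(path.with_suffix(".csv"), index=False)
    return fig


def plot_surprisal_traces(logs, cfg: Optional[SurprisalConfig] = None,
                          path: Optional[Path] = None):
    """Per-round surprisal of a few dyads: conventions show as falling traces."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.2))
    rows = []
    for log in logs:
        series = stability(log, cfg).series
        ax.plot(series, alpha=0.7, label=f"dyad {log.dyad_id}")
        rows.append(pd.DataFrame({"dyad_id": log.dyad_id,
                                  "round": range(len(series)),
                                  "surprisal": series}))
    ax.set_xlabel("round")
    ax.set_ylabel("surprisal")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, dpi=150)
        pd.concat(rows).to_csv(path.with_suffix(".csv"), index=False)
    return fig
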