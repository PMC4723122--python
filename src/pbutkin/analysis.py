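"""Cross-solute analysis and report rendering.

The central analysis correlates the percentage of protein binding with each
kinetic quantity (dialyzer clearance K, plasmatic volume V1, total
distribution volume Vtot, intercompartment clearance K21) across the solute
panel, using one central value per solute, so the sample size equals the
number of solutes.  The PB-K21 correlation is optionally recomputed without
p-cresylglucuronide, whose low K21 despite near-zero binding dominates the
full-panel value.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .strategies import AdequacyReport

__all__ = ["correlate_binding", "table_shaped_report", "plot_intradialytic", "plot_adequacy"]

KINETIC_QUANTITIES = ("K", "V1", "Vtot", "K21")


def correlate_binding(
    param_table: pd.DataFrame,
    quantities: Sequence[str] = KINETIC_QUANTITIES,
    subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of protein binding with kinetic quantities.

    ``param_table`` holds one row per solute (index = solute) with a ``PB``
    column and one column per kinetic quantity.  ``subset`` restricts the
    solutes (e.g. dropping PCG for the K21 correlation).  Returns a frame
    with columns quantity, R, p, n, solutes.

    Refuses to correlate fewer than three solutes.
    """
    table = param_table.loc[list(subset)] if subset is not None else param_table
    if len(table) < 3:
        raise ValueError(f"need at least 3 solutes, got {len(table)}")
    if "PB" not in table.columns:
        raise KeyError("param_table must have a 'PB' column")
    rows = []
    for q in quantities:
        r, p = pearsonr(table["PB"].to_numpy(float), table[q].to_numpy(float))
        rows.append(
            {"quantity": q, "R": r, "p": p, "n": len(table), "solutes": ",".join(table.index)}
        )
    return pd.DataFrame(rows)


def table_shaped_report(report: AdequacyReport) -> dict[str, pd.DataFrame]:
    """Strategy-by-solute matrices of TSR, TAC1 and C1_pre (canonical units)."""
    return {metric: report.to_wide(metric) for metric in AdequacyReport.METRICS}


def plot_intradialytic(trajectories: dict, path=None):
    """Panel of simulated C1/C2 session profiles, one subplot per solute."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(trajectories)
    ncols = min(n, 3)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False)
    for ax, (solute, traj) in zip(axes.ravel(), trajectories.items()):
        ax.plot(traj.time_grid, traj.C1, lw=2, label="C1 (plasmatic)")
        ax.plot(traj.time_grid, traj.C2, lw=1, label="C2 (extraplasmatic)")
        ax.set_title(solute)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("concentration (mg/L)")
        ax.legend(fontsize=8)
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_adequacy(report: AdequacyReport, solutes=("HA", "IS"), path=None):
    """Grouped bars of TSR, TAC1 and C1_pre per strategy for selected solutes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = AdequacyReport.METRICS
    fig, axes = plt.subplots(1, len(metrics), figsize=(5 * len(metrics), 4))
    for ax, metric in zip(np.atleast_1d(axes), metrics):
        wide = report.to_wide(metric)
        sub = wide[[s for s in solutes if s in wide.columns]]
        sub.plot.bar(ax=ax, legend=True)
        ax.set_title(metric)
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
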