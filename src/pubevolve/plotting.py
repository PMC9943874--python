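"""Minimal trajectory plotting (requires matplotlib)."""

from __future__ import annotations

import pandas as pd

from .engine import Trajectory

DEFAULT_FIELDS = ("mean_effort", "mean_replication_rate", "mean_alpha", "fdr")


def plot_trajectory(trajectory: Trajectory | pd.DataFrame, fields=DEFAULT_FIELDS,
                    ax=None, **kwargs):
    """Line plot of selected metrics against the time step.

    Effort is drawn on a secondary axis (its scale dwarfs the probabilities).
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    df = trajectory.data if isinstance(trajectory, Trajectory) else trajectory
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    ax2 = None
    for field in fields:
        if field == "mean_effort":
            ax2 = ax.twinx()
            ax2.plot(df["step"], df[field], color="tab:gray", ls="--",
                     label=field, **kwargs)
            ax2.set_ylabel("mean effort")
        else:
            ax.plot(df["step"], df[field], label=field, **kwargs)
    ax.set_xlabel("time step")
    ax.set_ylabel("probability / rate")
    ax.set_ylim(-0.02, 1.02)
    handles, labels = ax.get_legend_handles_labels()
    if ax2 is not None:
        h2, l2 = ax2.get_legend_handles_labels()
        handles += h2
        labels += l2
    ax.legend(handles, labels, loc="center right", fontsize=8)
    return ax
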