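"""Minimal trajectory plotting helper."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt


def plot_trajectory(result, segments=("head", "chest"), ax=None):
    """Plot head-core and mean-skin temperature over a run.

    Returns the matplotlib figure.  Shaded bands mark the stage boundaries.
    """
    if ax is None:
        fig, ax = plt.subplots(figsize=(8, 4.5))
    else:
        fig = ax.figure
    t_min = result.times / 60.0
    idx = {n: j for j, n in enumerate(result.model.names)}
    for name in segments:
        ax.plot(t_min, result.T_cr[:, idx[name]], label=f"{name} core")
    ax.plot(t_min, result.T_sk_mean, "--", label="mean skin")
    edge = 0.0
    for st in result.scenario.environment.stages[:-1]:
        edge += st.duration / 60.0
        ax.axvline(edge, color="0.8", lw=0.8, zorder=0)
    ax.set_xlabel("time, min")
    ax.set_ylabel("temperature, °C")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    return fig
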