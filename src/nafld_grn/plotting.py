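"""Convenience plots: level distributions, bifurcation diagrams, trajectories."""

from __future__ import annotations

import numpy as np

from nafld_grn.stability import BifurcationBranch, Trajectory


def plot_level_densities(levels, nodes, ax=None):
    """KDE of pooled z-normalized log2 levels, one curve per gene."""
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    from nafld_grn.states import z_normalize

    if ax is None:
        _, ax = plt.subplots()
    grid = np.linspace(-3, 3, 400)
    for j, name in enumerate(nodes):
        z = z_normalize(np.asarray(levels)[:, j]).z
        ax.plot(grid, gaussian_kde(z)(grid), label=name)
    ax.set_xlabel("z-normalized log2 level")
    ax.set_ylabel("density")
    ax.legend()
    return ax


def plot_bifurcation(branch: BifurcationBranch, node: str, ax=None):
    """Stable branches solid, unstable dotted, vs the swept parameter."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = branch.table
    for bid, sub in t.groupby("branch"):
        for stable, style in ((True, "-"), (False, ":")):
            seg = sub[sub["stable"] == stable].sort_values("value")
            if len(seg):
                ax.plot(seg["value"], seg[node], style,
                        color="tab:blue" if stable else "tab:red")
    ax.set_xlabel(branch.parameter)
    ax.set_ylabel(f"{node} level")
    return ax


def plot_trajectory(traj: Trajectory, nodes=None, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name in nodes or traj.nodes:
        j = traj.nodes.index(name)
        ax.plot(traj.time, traj.levels[:, j], label=name, lw=0.6)
    ax.set_xlabel("time (hr)")
    ax.set_ylabel("level (1e6 molecules)")
    ax.legend()
    return ax
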