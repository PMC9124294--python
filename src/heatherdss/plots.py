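"""Plots: outcome densities, SERF curves, signed VIP bars."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_outcome_distributions", "plot_serf", "plot_vip"]


def _pyplot():
    import matplotlib

    if matplotlib.get_backend().lower() not in ("agg", "module://matplotlib_inline.backend_inline"):
        try:
            matplotlib.use("Agg")
        except Exception:  # pragma: no cover - interactive sessions
            pass
    import matplotlib.pyplot as plt

    return plt


def plot_outcome_distributions(result, outcomes=None, ax=None):
    """Kernel-density curves of NPV outcome distributions."""
    from scipy.stats import gaussian_kde

    plt = _pyplot()
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    outcomes = list(outcomes) if outcomes is not None else list(result.outputs.columns)
    for name in outcomes:
        values = result.outcome(name)
        kde = gaussian_kde(values)
        grid = np.linspace(values.min(), values.max(), 400)
        density = kde(grid)
        ax.plot(grid, density / density.max(), label=name)
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("Net present value (€)")
    ax.set_ylabel("Scaled density")
    ax.legend(frameon=False)
    return ax.figure


def plot_serf(analysis, axes=None):
    """Two-panel SERF plot: linear CE axis and log axis (positive CEs only)."""
    plt = _pyplot()
    if axes is None:
        _, axes = plt.subplots(2, 1, figsize=(7, 7), sharex=True)
    grid = analysis.grid
    positions = np.arange(len(grid))
    for name in analysis.table.columns:
        ce = analysis.table[name].to_numpy()
        axes[0].plot(positions, ce, marker="o", ms=3, label=name)
        positive = np.where(ce > 0, ce, np.nan)
        axes[1].plot(positions, positive, marker="o", ms=3, label=name)
    axes[1].set_yscale("log")
    labels = [f"{r:.0e}" if r != 0 else "0" for r in grid]
    axes[1].set_xticks(positions, labels, rotation=45, fontsize=7)
    axes[0].set_ylabel("Certainty equivalent (€)")
    axes[1].set_ylabel("CE (€, log scale)")
    axes[1].set_xlabel("Risk-aversion coefficient $r_a$")
    axes[0].axhline(0.0, color="grey", lw=0.8, ls="--")
    axes[0].legend(frameon=False)
    return axes[0].figure


def plot_vip(report, ax=None, threshold: float = 1.0):
    """Horizontal VIP bars (VIP > threshold only), colored by influence sign."""
    plt = _pyplot()
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    frame = report.ranked()
    frame = frame[frame["vip"] > threshold]
    colors = ["tab:blue" if s == "+" else "tab:orange" for s in frame["sign"]]
    ax.barh(frame.index[::-1], frame["vip"][::-1], color=colors[::-1])
    ax.axvline(threshold, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("VIP score")
    if report.decision:
        ax.set_title(f"Variable importance: {report.decision}")
    ax.figure.tight_layout()
    return ax.figure
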