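"""Plots: POP coefficients vs phase, polar phase maps, survival curves."""

from __future__ import annotations

import numpy as np

from .dynamics import GenePopTable
from .stats import ThresholdReport

__all__ = ["plot_pop_coefficients", "plot_polar", "plot_survival_curves"]


def _get_axes(ax=None, **subplot_kw):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw=subplot_kw)
    return ax


def plot_pop_coefficients(table: GenePopTable, axes=None):
    """Scatter c1 and c2 against phase with their cosine/sine envelopes.

    Genes with large coefficients trace out a cosine envelope on the
    first pattern and a sine envelope on the second — the signature of a
    clean rotation on the POP plane.
    """
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    theta = np.linspace(0, 360, 361)
    rmax = float(table.amplitude.max())
    for ax, coef, env, label in (
        (axes[0], table.c1, np.cos(np.radians(theta)), "c1 (cosine pattern)"),
        (axes[1], table.c2, np.sin(np.radians(theta)), "c2 (sine pattern)"),
    ):
        ax.scatter(table.phase_deg, coef, s=4, alpha=0.4)
        ax.plot(theta, rmax * env, "k--", lw=1)
        ax.plot(theta, -rmax * env, "k--", lw=1)
        ax.set_xlabel("POP phase (deg)")
        ax.set_ylabel(label)
        ax.set_xlim(0, 360)
    return axes


def plot_polar(table: GenePopTable, groups: dict[str, str] | None = None, ax=None):
    """Genes as points (amplitude, phase) in polar coordinates.

    ``groups`` optionally maps gene id -> label; labelled genes are
    colored per label, others drawn faintly in grey.
    """
    ax = _get_axes(ax, projection="polar")
    theta = np.radians(table.phase_deg)
    if groups:
        idx = {g: i for i, g in enumerate(table.gene_ids)}
        labelled = {g for g in groups if g in idx}
        rest = [i for g, i in idx.items() if g not in labelled]
        ax.scatter(theta[rest], table.amplitude[rest], s=3, c="lightgrey", alpha=0.5)
        for label in sorted(set(groups.values())):
            sel = [idx[g] for g in labelled if groups[g] == label]
            if sel:
                ax.scatter(theta[sel], table.amplitude[sel], s=12, label=label)
        ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.05), fontsize=8)
    else:
        ax.scatter(theta, table.amplitude, s=3, alpha=0.5)
    ax.set_title("POP amplitude and phase")
    return ax


def plot_survival_curves(report: ThresholdReport, ax=None):
    """Survival curves P(amplitude > a), log y-scale, with the threshold."""
    ax = _get_axes(ax)
    ax.plot(report.grid, report.s_all, label="all genes")
    ax.plot(report.grid, report.s_excl, "--", label="excluding reference set")
    if report.threshold is not None:
        ax.axvline(report.threshold, color="k", lw=1, ls=":",
                   label=f"threshold = {report.threshold:.3g}")
    ax.set_yscale("log")
    ax.set_xlabel("POP amplitude a")
    ax.set_ylabel("P(amplitude > a)")
    ax.legend()
    return ax
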