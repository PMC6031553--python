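"""Bland-Altman and error-sweep figures."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .stats import MethodComparison, PairedCycleDiff, SweepResult

__all__ = ["plot_bland_altman_grid", "plot_sweep"]


def plot_bland_altman_grid(
    diffs_by_method: Mapping[str, Sequence[PairedCycleDiff]],
    comparisons: Mapping[str, MethodComparison],
    means_by_method: Mapping[str, Sequence[float]],
    path: str | Path,
) -> Path:
    """Per-method panels of relative per-cycle difference vs mean dose, with
    the mean difference (solid) and limits of agreement (dashed)."""
    methods = sorted(diffs_by_method)
    ncol = min(4, max(1, len(methods)))
    nrow = -(-len(methods) // ncol)
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(3.2 * ncol, 2.8 * nrow), squeeze=False, sharey=True
    )
    for ax in axes.flat[len(methods):]:
        ax.set_axis_off()
    for ax, mid in zip(axes.flat, methods):
        diffs = diffs_by_method[mid]
        comp = comparisons[mid]
        ax.scatter(means_by_method[mid], [d.rel_diff for d in diffs], s=10, alpha=0.6)
        ax.axhline(comp.mean_diff, color="k", lw=1)
        for y in (comp.loa_low, comp.loa_high):
            ax.axhline(y, color="k", lw=1, ls="--")
        ax.set_title(f"{mid}: {comp.mean_diff:.0f} ± {comp.loa_high - comp.mean_diff:.0f} %")
        ax.set_xlabel("mean AD/cycle (Gy)")
    axes[0, 0].set_ylabel("relative difference (%)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_sweep(sweep: SweepResult, path: str | Path) -> Path:
    """Theoretical error E1 and patient-based error E2 (mean, SD, RMSD) as a
    function of the single imaging time."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.plot(sweep.t_ref, sweep.e1, "k--", label="$E_1$ (theory)")
    ax.plot(sweep.t_ref, sweep.e2_mean, color="grey", label="mean $E_2$")
    ax.plot(sweep.t_ref, sweep.e2_sd, color="green", label="SD $E_2$")
    ax.plot(sweep.t_ref, sweep.e2_rmsd, color="red", label="RMSD $E_2$")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("single imaging time $t_{ref}$ (h)")
    ax.set_ylabel("fractional deviation (%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
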