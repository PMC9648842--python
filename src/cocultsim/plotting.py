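"""Plotting of trajectories and coexistence scans (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .reactor import Trajectory
from .scenarios import ScanResult, biomass_fractions

PATHWAY_COLOURS = {
    "glu_ferm": "tab:cyan",
    "ace": "gold",
    "eth": "purple",
    "glu_ox": "tab:green",
}


def plot_trajectory(traj: Trajectory, path=None):
    """Time series panel: biomass + metabolites, enzymes, growth rates."""
    fig, axes = plt.subplots(3, 1, figsize=(8, 9), sharex=True)
    ax = axes[0]
    for k, name in enumerate(traj.species_names):
        ax.plot(traj.t, traj.X[:, k], label=f"X {name}")
    for j, m in enumerate(traj.metabolites):
        ax.plot(traj.t, traj.M[:, j], "--", label=m)
    ax.set_ylabel("g/L")
    ax.legend(fontsize=8)
    ax = axes[1]
    for k, name in enumerate(traj.species_names):
        for j, pid in enumerate(traj.pathway_ids[k]):
            ax.plot(
                traj.t,
                traj.psi_rel[k][:, j],
                color=PATHWAY_COLOURS.get(pid),
                alpha=0.6 + 0.4 * (k == 0),
                label=f"{name}:{pid}",
            )
    ax.set_ylabel(r"$\Psi_{rel}$")
    ax.legend(fontsize=7, ncol=2)
    ax = axes[2]
    for k, name in enumerate(traj.species_names):
        ax.plot(traj.t, traj.mu_total[:, k], label=f"mu {name}")
    ax.plot(traj.t, traj.D, "k:", label="D(t)")
    ax.set_xlabel("time, h")
    ax.set_ylabel(r"$h^{-1}$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_fractions(traj: Trajectory, path=None):
    """Species biomass-fraction time series of a co-culture run."""
    frac = biomass_fractions(traj)
    fig, ax = plt.subplots(figsize=(8, 3.5))
    for name in traj.species_names:
        ax.plot(frac["t"], frac[f"frac_{name}"], label=name)
    ax.set_xlabel("time, h")
    ax.set_ylabel("biomass fraction")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_scan(scan: ScanResult, species_name: str, path=None):
    """Heat maps of a species' averaged final fraction over (w, s), per D."""
    df = scan.to_frame()
    n_D = len(scan.D_grid)
    fig, axes = plt.subplots(1, n_D, figsize=(3 * n_D, 3), squeeze=False)
    for i, D in enumerate(scan.D_grid):
        sub = df[np.isclose(df["D"], D)]
        grid = sub.pivot(index="w", columns="s", values=f"frac_{species_name}")
        ax = axes[0, i]
        im = ax.imshow(
            grid.to_numpy(),
            origin="lower",
            vmin=0,
            vmax=1,
            extent=(
                scan.s_grid.min(),
                scan.s_grid.max(),
                scan.w_grid.min(),
                scan.w_grid.max(),
            ),
            aspect="auto",
            cmap="viridis",
        )
        ax.set_title(f"D = {D} 1/h", fontsize=9)
        ax.set_xlabel("s")
        if i == 0:
            ax.set_ylabel("w, 1/h")
    fig.colorbar(im, ax=axes[0, -1], label=f"fraction {species_name}")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
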