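"""Convenience figures: trajectory panels, zone maps, resource sweeps.

Figures are side outputs; the CSV exports are the contract.
"""

from __future__ import annotations

import numpy as np

from .dynamics import Trajectory
from .equilibrium import ResourceSweep, ZoneMap

_ZONE_COLORS = {"coexist_iv": "#2ca02c", "coexist_i": "#98df8a",
                "pro_only": "#1f77b4", "syn_only": "#d62728",
                "none": "#cccccc"}


def plot_trajectory(traj: Trajectory, ax=None, title: str | None = None):
    """Abundances (log scale, left axis) and nutrients (right axis) vs time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.semilogy(traj.times, traj.values[:, 0], "-", color="#1f77b4",
                label="Prochlorococcus")
    ax.semilogy(traj.times, traj.values[:, 1], "-", color="#d62728",
                label="Synechococcus")
    ax.set_xlabel("time (d)")
    ax.set_ylabel("abundance (cells L$^{-1}$)")
    ax2 = ax.twinx()
    ax2.plot(traj.times, traj.values[:, 2], "--", color="#2ca02c",
             label="NO$_3^-$")
    ax2.plot(traj.times, traj.values[:, 3], "--", color="#ff7f0e",
             label="NH$_4^+$")
    ax2.set_ylabel("concentration (nmol L$^{-1}$)")
    h1, l1 = ax.get_legend_handles_labels()
    h2, l2 = ax2.get_legend_handles_labels()
    ax.legend(h1 + h2, l1 + l2, fontsize=8, loc="best")
    if title:
        ax.set_title(title)
    return ax


def plot_zone_map(zmap: ZoneMap, ax=None):
    """Coexistence domains and biomass ratio over K-ratio space."""
    import matplotlib.colors as mcolors
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 4.5))
    r3, r4 = zmap.ratio_no3_axis, zmap.ratio_nh4_axis
    zone_idx = np.vectorize(list(_ZONE_COLORS).index)(zmap.zones)
    cmap = mcolors.ListedColormap(list(_ZONE_COLORS.values()))
    ax.pcolormesh(r4, r3, zone_idx, cmap=cmap, vmin=0,
                  vmax=len(_ZONE_COLORS) - 1, shading="nearest")
    mask = zmap.coexistence_mask()
    if mask.any():
        pc = ax.pcolormesh(
            r4, r3, np.where(mask, np.log10(zmap.biomass_ratio), np.nan),
            cmap="viridis", shading="nearest")
        plt.colorbar(pc, ax=ax, label="log$_{10}$ N$_{Pro}$/N$_{Syn}$")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("K$_{NH4}^{Pro}$ / K$_{NH4}^{Syn}$")
    ax.set_ylabel("K$_{NO3}^{Pro}$ / K$_{NO3}^{Syn}$")
    return ax


def plot_resource_sweep(sweep: ResourceSweep, ax=None):
    """Equilibrium N_Pro/N_Syn along the supply ratio SNO3/SNH4."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 4))
    ax.loglog(sweep.s_ratio_axis, sweep.biomass_ratio, "o-", ms=3)
    ax.set_xlabel("S$_{NO3}$ / S$_{NH4}$")
    ax.set_ylabel("N$_{Pro}$ / N$_{Syn}$")
    return ax
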