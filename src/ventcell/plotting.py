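"""Basic matplotlib views of trajectories and sweeps (no styling ambitions)."""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_free_energy", "plot_sweep"]


def plot_free_energy(timeseries: pd.DataFrame, path: str | None = None):
    """Reported and per-ion -dG plus internal pH against time."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax, ax_ph) = plt.subplots(
        2, 1, sharex=True, figsize=(7, 5), height_ratios=[2, 1]
    )
    ax.plot(timeseries["t"], timeseries["minus_dg_reported"], label="-dG reported")
    ax.plot(timeseries["t"], timeseries["minus_dg_h"], "--", label="-dG (H+)")
    ax.plot(timeseries["t"], timeseries["minus_dg_na"], ":", label="-dG (Na+)")
    ax.set_ylabel("-dG (kJ/mol)")
    ax.legend(frameon=False)
    ax_ph.plot(timeseries["t"], timeseries["ph_internal"], color="k")
    ax_ph.set_xlabel("time (s)")
    ax_ph.set_ylabel("internal pH")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_sweep(table: pd.DataFrame, x: str, path: str | None = None):
    """Steady -dG against one swept parameter (log x when numeric)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    xs = pd.to_numeric(table[x], errors="coerce")
    ax.plot(xs, table["minus_dg_reported"], "o-")
    if (xs > 0).all():
        ax.set_xscale("log")
    ax.set_xlabel(x)
    ax.set_ylabel("steady -dG (kJ/mol)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
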