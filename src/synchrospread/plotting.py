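"""Optional heat-map rendering of mean fields (requires matplotlib)."""

from __future__ import annotations

import numpy as np

from .wavelet import MeanField

__all__ = ["plot_mean_field"]


def plot_mean_field(
    mf: MeanField,
    ax=None,
    cutoff_years: float = 4.0,
    contour_level: float | None = None,
    cmap: str = "viridis",
):
    """Time x timescale magnitude heat map with the short/long cutoff line.

    COI-masked cells are dimmed; ``contour_level`` draws the WPMF
    significance contour when given.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mag = np.abs(mf.values)
    periods = mf.grid.periods
    years = mf.years if mf.years is not None else np.arange(mag.shape[0])
    masked = np.ma.masked_where(mf.coi, mag)
    mesh = ax.pcolormesh(years, periods, masked.T, cmap=cmap, shading="nearest")
    ax.set_yscale("log")
    ax.set_ylabel("timescale (yr)")
    ax.set_xlabel("year")
    ax.axhline(cutoff_years, color="white", lw=1.5)
    if contour_level is not None:
        ax.contour(
            years, periods, np.where(mf.coi, 0.0, mag).T,
            levels=[contour_level], colors="black", linewidths=1.0,
        )
    ax.figure.colorbar(mesh, ax=ax, label=f"|{mf.kind.upper()}|")
    return ax
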