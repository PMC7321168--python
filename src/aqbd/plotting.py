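"""Rendering of sweet-spot and design-space maps (2-D slices)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless rendering; callers embed or save
import matplotlib.pyplot as plt
import numpy as np

from .criteria import SweetSpotMap, contour_slices
from .modr import ModrMap

__all__ = ["plot_sweet_spot", "plot_modr"]

_CLASS_COLORS = {"all_met": "#3cb44b", "one_failed": "#9fd8f5", "multi_failed": "white"}


def _grid_arrays(table, grid, column):
    (xname, yname) = list(grid.free)
    nx, ny = grid.shape
    x = table[xname].to_numpy().reshape(nx, ny)
    y = table[yname].to_numpy().reshape(nx, ny)
    z = table[column].to_numpy().reshape(nx, ny)
    return xname, yname, x, y, z


def plot_sweet_spot(sweet_map: SweetSpotMap, ax=None):
    """Overlay classes in the usual colouring: green where every criterion
    is met, light blue where exactly one fails, white elsewhere."""
    classes = contour_slices(sweet_map)
    code = classes["class"].map(
        {"multi_failed": 0, "one_failed": 1, "all_met": 2}
    ).to_numpy()
    t = sweet_map.table.copy()
    t["_class"] = code
    xname, yname, x, y, z = _grid_arrays(t, sweet_map.grid, "_class")
    if ax is None:
        _, ax = plt.subplots()
    cmap = matplotlib.colors.ListedColormap(
        [_CLASS_COLORS["multi_failed"], _CLASS_COLORS["one_failed"],
         _CLASS_COLORS["all_met"]]
    )
    ax.pcolormesh(x, y, z, cmap=cmap, vmin=0, vmax=2, shading="nearest")
    ax.set_xlabel(xname)
    ax.set_ylabel(yname)
    ax.set_title("sweet spot (all criteria met in green)")
    return ax


def plot_modr(modr: ModrMap, ax=None, optimum=None):
    """Pass-probability surface with the MODR boundary contoured at the
    probability threshold; optionally marks an optimum setpoint."""
    xname, yname, x, y, z = _grid_arrays(modr.table, modr.grid, "probability")
    if ax is None:
        _, ax = plt.subplots()
    pc = ax.pcolormesh(x, y, z, cmap="viridis", vmin=0, vmax=1, shading="nearest")
    plt.colorbar(pc, ax=ax, label="P(all criteria met)")
    ax.contour(
        x, y, z, levels=[modr.settings.threshold], colors="white",
        linestyles="dashed",
    )
    if optimum is not None:
        ax.plot(
            optimum.settings[xname], optimum.settings[yname], "rx", markersize=10
        )
    ax.set_xlabel(xname)
    ax.set_ylabel(yname)
    ax.set_title(f"design space (MODR) at {modr.settings.threshold:.0%}")
    return ax
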