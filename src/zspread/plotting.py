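"""Optional plots: coverage heat maps and per-well summary traces.

Requires matplotlib (``pip install zspread[plot]``); nothing else in
the package depends on this module.
"""

from __future__ import annotations

import numpy as np

from .analysis import DEFAULT_COVERAGE_THRESHOLD, WellSummary, coverage_map
from .recording import Recording

__all__ = ["plot_coverage_map", "plot_summary_traces"]


def plot_coverage_map(
    rec: Recording,
    t: float,
    threshold: float = DEFAULT_COVERAGE_THRESHOLD,
    ax=None,
    vmax: float | None = None,
):
    """Colour-coded map of per-electrode maximum relative impedance at
    one time point; uncovered electrodes are blanked."""
    import matplotlib.pyplot as plt

    grid = coverage_map(rec, t, threshold)
    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 3.6))
    im = ax.imshow(
        grid,
        origin="lower",
        cmap="viridis",
        vmin=0.0,
        vmax=vmax,
        interpolation="nearest",
    )
    for (r, c), v in np.ndenumerate(grid):
        if np.isfinite(v):
            ax.text(c, r, f"{v:.0f}", ha="center", va="center", fontsize=6)
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    ax.set_title(f"{rec.well_id} at {t:g} h (max rel. impedance, %)")
    plt.colorbar(im, ax=ax, shrink=0.8)
    return ax


def plot_summary_traces(summaries: list[WellSummary], axes=None):
    """Covered-electrode counts and covered-only medians over time,
    one line per well."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(8, 3), sharex=True)
    for s in summaries:
        axes[0].plot(s.time_points_h, s.covered_count, marker="o", label=s.label or s.well_id)
        axes[1].plot(
            s.time_points_h, s.median_max_rel_impedance, marker="o",
            label=s.label or s.well_id,
        )
    axes[0].set_ylabel("covered electrodes")
    axes[1].set_ylabel("median max rel. impedance (%)")
    for ax in axes:
        ax.set_xlabel("time (h)")
    axes[0].legend(fontsize=7)
    return axes
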