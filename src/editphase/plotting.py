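"""Optional matplotlib views of profiles and fits (needs the ``plot`` extra)."""

from __future__ import annotations

import pandas as pd

from .correlation import FitResult


def stacked_profile_bars(matrix: pd.DataFrame, ax=None):
    """One stacked bar per cell from a sorted profile matrix (rows sum to 100)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, len(matrix) / 12), 4))
    bottom = None
    x = range(len(matrix))
    for variant in matrix.columns:
        vals = matrix[variant].to_numpy()
        ax.bar(x, vals, bottom=bottom, width=1.0, label=variant)
        bottom = vals if bottom is None else bottom + vals
    ax.set_xlim(-0.5, len(matrix) - 0.5)
    ax.set_ylim(0, 100)
    ax.set_ylabel("% of phased reads")
    ax.set_xlabel("cell (sorted by unedited %)")
    ax.legend(fontsize="x-small", ncol=2)
    return ax


def expression_scatter(x, y, fit: FitResult, ax=None):
    """Edit percent vs TPM scatter with the OLS line and its 95% band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(x, y, s=12, alpha=0.7)
    ax.plot(fit.x_grid, fit.predict(fit.x_grid), color="black")
    ax.fill_between(fit.x_grid, fit.band_low, fit.band_high, color="gray", alpha=0.4)
    ax.set_xlabel("expression (TPM)")
    ax.set_ylabel("edit percent")
    return ax
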