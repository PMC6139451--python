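"""Minimal field/filter heat-map helper."""

from __future__ import annotations

import numpy as np


def field_heatmap(field: np.ndarray, ax=None, title: str | None = None,
                  origin_marker: tuple | None = None):
    """Symmetric-scale heat map of an RF, CF, or LN filter grid (bars x lags,
    most recent lag rightmost).  Returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    field = np.asarray(field, float)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    v = np.max(np.abs(field)) or 1.0
    im = ax.imshow(field, cmap="RdBu_r", vmin=-v, vmax=v, aspect="auto",
                   interpolation="nearest")
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    if origin_marker is not None:
        ax.plot(origin_marker[1], origin_marker[0], "k+", ms=10)
    ax.set_xlabel("lag (oldest to newest)")
    ax.set_ylabel("bar")
    if title:
        ax.set_title(title)
    return ax
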