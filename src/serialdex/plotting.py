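"""Minimal plots: Kaplan-Meier step curves and an expression heatmap.

Illustrative only — publication styling is out of scope.  matplotlib is
imported lazily so headless/pipeline use never touches a display backend.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .datamodel import ExpressionMatrix
from .survival import KMCurve


def plot_km(curves: Sequence[KMCurve], ax=None, title: str = ""):
    """Step plot of one or more product-limit curves; returns the axes."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for curve in curves:
        t = np.r_[0.0, curve.times]
        s = np.r_[1.0, curve.survival]
        ax.step(t, s, where="post", label=f"{curve.label} (n={curve.n}, events={curve.n_events})")
    ax.set_xlabel("time (months)")
    ax.set_ylabel("recurrence-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    return ax


def plot_heatmap(matrix: ExpressionMatrix, features: Sequence[str] | None = None, ax=None):
    """Features x samples heatmap of log2 ratios (blue low, red high)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    data = matrix.data if features is None else matrix.data.loc[list(features)]
    if ax is None:
        _, ax = plt.subplots()
    lim = float(np.nanmax(np.abs(data.to_numpy()))) or 1.0
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.set_xlabel("samples")
    ax.set_ylabel("features")
    ax.figure.colorbar(im, ax=ax, label="log2 ratio")
    return ax
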