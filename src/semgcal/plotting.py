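"""Optional plots (requires matplotlib, installed via the ``plot`` extra)."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_average_accuracy", "plot_pca_sessions"]


def plot_average_accuracy(aa: pd.Series, fit, ax=None, label: str = ""):
    """Average-accuracy marginal with its logarithmic fit overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = aa.index.to_numpy(dtype=float)
    ax.plot(x, aa.to_numpy(), "o", label=f"{label} AA")
    xf = np.linspace(x.min(), x.max(), 200)
    ax.plot(xf, fit.slope * np.log(xf) + fit.intercept, "-",
            label=f"y = {fit.slope:.2f} ln(x) + {fit.intercept:.2f} (R²={fit.r_squared:.3f})")
    ax.set_xlabel(label or "amount of training data")
    ax.set_ylabel("average accuracy (%)")
    ax.legend()
    return ax


def plot_pca_sessions(projection, sessions, ax=None):
    """First three principal-component scores colored by session."""
    import matplotlib.pyplot as plt

    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="3d")
    sessions = np.asarray(sessions)
    for s in np.unique(sessions):
        pts = projection.scores[sessions == s]
        ax.scatter(pts[:, 0], pts[:, 1], pts[:, 2], s=4, label=f"session {s}")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_zlabel("PC3")
    ax.legend()
    return ax
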