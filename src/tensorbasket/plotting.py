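"""Optional matplotlib figures: scree curves, profile heat maps, trajectories."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import TensorPCAResults
from .order_selection import OrderSelectionResult
from .patterns import cluster_loadings


def plot_scree(results: TensorPCAResults, ax=None):
    """Eigenvalue scree curves for both modes on one axis pair."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(1, 2, figsize=(9, 3.2))
    for a, lam, title in zip(
        ax,
        (results.eigenvalues_products, results.eigenvalues_weeks),
        ("product groups", "weeks"),
    ):
        a.plot(np.arange(1, lam.size + 1), lam, marker="o", ms=3)
        a.set_xlabel("component")
        a.set_ylabel("eigenvalue")
        a.set_title(title)
    return ax


def plot_order_criterion(result: OrderSelectionResult, ax=None):
    """The augmentation criterion g(k) with its components."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    k = np.arange(result.criterion.size)
    ax.plot(k, result.criterion, marker="o", ms=3, label="g(k)")
    ax.plot(k, result.eigen_term, ls="--", label="eigenvalue term")
    ax.plot(k, result.variation_term, ls=":", label="variation term")
    ax.axvline(result.k_hat, color="grey", lw=0.8)
    ax.set_xlabel("k")
    ax.legend()
    return ax


def plot_profile_heatmap(profile: pd.DataFrame, ax=None, cluster_rows: bool = True):
    """Heat map of a standardized group profile, rows ordered by clustering."""
    import matplotlib.pyplot as plt

    if cluster_rows and profile.shape[0] > 2:
        order, _ = cluster_loadings(profile)
        profile = profile.iloc[order]
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.3 * profile.shape[0] + 1.5))
    vmax = float(np.nanmax(np.abs(profile.to_numpy()))) or 1.0
    im = ax.imshow(profile.to_numpy(), aspect="auto", cmap="PiYG", vmin=-vmax, vmax=vmax)
    ax.set_yticks(range(profile.shape[0]), profile.index)
    ax.set_xlabel("week")
    ax.figure.colorbar(im, ax=ax, label="z score")
    return ax


def plot_trajectories(trajectories: pd.DataFrame, ax=None):
    """Weekly subset-percentage curves, one line per decile."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    cmap = plt.get_cmap("viridis")
    for i, (dec, row) in enumerate(trajectories.iterrows()):
        ax.plot(trajectories.columns, row, color=cmap(i / 9), label=f"decile {dec}", lw=1)
    ax.set_xlabel("week")
    ax.set_ylabel("% of weekly expenditure")
    ax.legend(ncol=2, fontsize=7)
    return ax
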