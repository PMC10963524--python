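"""Presentation-only KDE and box-plot rendering (requires matplotlib)."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd


def _mpl():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def kde_grid(groups: dict, columns: Sequence[str], out_png: str,
             bw: Optional[float] = None) -> None:
    """Per-column Gaussian-KDE overlays of several labeled sample tables.

    ``groups`` maps label -> DataFrame; one panel per column.
    """
    from scipy.stats import gaussian_kde

    plt = _mpl()
    n = len(columns)
    ncol = min(4, n)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow),
                             squeeze=False)
    for i, col in enumerate(columns):
        ax = axes[i // ncol][i % ncol]
        for label, df in groups.items():
            x = np.asarray(df[col], float)
            if np.ptp(x) == 0:
                ax.axvline(x[0], label=label)
                continue
            kde = gaussian_kde(x, bw_method=bw)
            grid = np.linspace(x.min(), x.max(), 200)
            ax.plot(grid, kde(grid), label=label)
        ax.set_title(col, fontsize=8)
    axes[0][0].legend(fontsize=7)
    for j in range(n, nrow * ncol):
        axes[j // ncol][j % ncol].axis("off")
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)


def feature_boxes(table: pd.DataFrame, by: str, columns: Sequence[str],
                  out_png: str) -> None:
    """Box plots of feature columns grouped by a label column."""
    plt = _mpl()
    labels = sorted(set(table[by]))
    n = len(columns)
    ncol = min(4, n)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow),
                             squeeze=False)
    for i, col in enumerate(columns):
        ax = axes[i // ncol][i % ncol]
        ax.boxplot([table.loc[table[by] == lb, col] for lb in labels],
                   tick_labels=labels)
        ax.set_title(col, fontsize=8)
        ax.tick_params(axis="x", labelrotation=45, labelsize=6)
    for j in range(n, nrow * ncol):
        axes[j // ncol][j % ncol].axis("off")
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
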