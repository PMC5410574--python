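"""Diagnostic figures: shape dictionaries and transition heatmaps."""

from __future__ import annotations

import numpy as np
from matplotlib.figure import Figure

__all__ = ["plot_dictionary", "plot_transition_heatmap"]


def plot_dictionary(dictionary, frequencies=None, path=None):
    """Grid of prototypes +/- one standard deviation, optionally with the
    per-step occurrence histogram of each shape underneath."""
    k = dictionary.k
    ncol = min(4, k)
    nrow = int(np.ceil(k / ncol)) * (2 if frequencies is not None else 1)
    fig = Figure(figsize=(3 * ncol, 2.2 * nrow))
    axes = fig.subplots(nrow, ncol, squeeze=False)
    for i in range(k):
        r, c = divmod(i, ncol)
        r *= 2 if frequencies is not None else 1
        ax = axes[r][c]
        proto = dictionary.prototypes[i]
        disp = dictionary.dispersions[i]
        x = np.arange(len(proto))
        ax.fill_between(x, proto - disp, proto + disp, alpha=0.3)
        ax.plot(x, proto, lw=1.2)
        ax.set_title(dictionary.labels[i])
        if frequencies is not None:
            axh = axes[r + 1][c]
            lab = dictionary.labels[i]
            if lab in frequencies.columns:
                axh.bar(range(len(frequencies)), frequencies[lab].to_numpy())
                axh.set_xticks(range(len(frequencies)))
                axh.set_xticklabels(frequencies.index, rotation=90, fontsize=6)
    for ax in np.ravel(axes)[k * (2 if frequencies is not None else 1):]:
        ax.set_visible(False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def plot_transition_heatmap(tm, path=None):
    """Heatmap of a row-stochastic transition matrix."""
    fig = Figure(figsize=(5, 4.2))
    ax = fig.subplots()
    im = ax.imshow(tm.probs, cmap="viridis", vmin=0.0)
    ax.set_xticks(range(len(tm.alphabet)))
    ax.set_xticklabels(tm.alphabet)
    ax.set_yticks(range(len(tm.alphabet)))
    ax.set_yticklabels(tm.alphabet)
    ax.set_xlabel("next symbol")
    ax.set_ylabel("current symbol")
    fig.colorbar(im, ax=ax, label="P(next | current)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
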