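"""Diagnostic plots: volcano, CTV histogram, and spatial co-occurrence traces."""

from __future__ import annotations

import numpy as np

from .lipidomics import FC_FLAG_THRESHOLD, SIGNIFICANCE_TIERS


def volcano(diff, species_class=None, ax=None):
    """Volcano plot of a differential-abundance table.

    Horizontal guides at p = 0.05 / 0.01 / 0.001, vertical guides at
    log2FC = +/-2; species with p <= 0.01 are colored by lipid class.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = diff["log2fc"].to_numpy()
    y = -np.log10(diff["p"].to_numpy())
    sig = diff["significant"].to_numpy()
    ax.scatter(x[~sig], y[~sig], s=10, c="0.7", label=None)
    if species_class is not None and sig.any():
        classes = species_class.reindex(diff.index).to_numpy()
        for cls in sorted(set(classes[sig])):
            m = sig & (classes == cls)
            ax.scatter(x[m], y[m], s=14, label=str(cls))
        ax.legend(fontsize=7, ncol=2)
    else:
        ax.scatter(x[sig], y[sig], s=14, c="C3")
    for thr in SIGNIFICANCE_TIERS:
        ax.axhline(-np.log10(thr), ls=":", c="0.4", lw=0.8)
    for v in (-FC_FLAG_THRESHOLD, FC_FLAG_THRESHOLD):
        ax.axvline(v, ls=":", c="0.4", lw=0.8)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    return ax


def ctv_histogram(events, results=None, channel: str = "ctv", ax=None, bins=200):
    """Log10 dye-intensity histogram with fitted generation centers overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    values = np.asarray(events[channel] if hasattr(events, "columns") else events)
    x = np.log10(values[values > 0])
    ax.hist(x, bins=bins, color="0.6")
    if results is not None:
        centers = results.mu0 - results.model.config.delta * np.arange(
            len(results.counts)
        )
        for i, c in enumerate(centers):
            ax.axvline(c, ls="--", c="C0", lw=0.8)
            ax.text(c, ax.get_ylim()[1] * 0.95, str(i), ha="center", fontsize=7)
    ax.set_xlabel("log10 dye intensity")
    ax.set_ylabel("events")
    return ax


def spatial_profile(traces: dict, ax=None):
    """Plot per-channel gray-value traces from ``coloc.intensity_profile``."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, trace in traces.items():
        ax.plot(trace, label=name)
    ax.set_xlabel("position along line (px)")
    ax.set_ylabel("gray value")
    ax.legend(fontsize=8)
    return ax
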