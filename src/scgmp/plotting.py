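"""Quick-look plots for ratio traces and classification summaries."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_ratio_trace", "plot_class_counts"]

_CLASS_COLORS = {
    "ANP_PREF": "tab:orange",
    "ANP_CNP": "tab:green",
    "CNP_PREF": "tab:cyan",
    "NONRESPONDER": "tab:gray",
    "EXCLUDED": "black",
}


def plot_ratio_trace(rt, protocol=(), ax=None):
    """Normalized ratio trace with stimulus windows shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    t = np.arange(len(rt.r))
    ax.plot(t, rt.r, color="black", lw=1)
    for ev in protocol:
        ax.axvspan(ev.start_frame, ev.end_frame, alpha=0.2, color="red")
        ax.text(
            ev.start_frame,
            ax.get_ylim()[1],
            f"{ev.drug} {ev.concentration:g}nM",
            fontsize=7,
            va="top",
        )
    ax.set_xlabel("frame")
    ax.set_ylabel("R / R$_0$")
    ax.set_title(f"{rt.roi} ({rt.qc_status.value})")
    return ax


def plot_class_counts(labels: dict, ax=None):
    """Bar chart of preference-class counts."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    order = [c for c in _CLASS_COLORS if c in set(labels.values())]
    counts = [sum(1 for v in labels.values() if v == c) for c in order]
    ax.bar(order, counts, color=[_CLASS_COLORS[c] for c in order])
    ax.set_ylabel("cells")
    ax.tick_params(axis="x", rotation=30)
    return ax
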