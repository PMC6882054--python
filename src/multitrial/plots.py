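"""Optional TPR-vs-FPR scatter plots over the aggregated rate tables."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["tpr_fpr_scatter"]

_MARKERS = {
    "sig2": "o", "ci_fixed": "+", "ci_dsl": "x", "ci_hksj": "*",
    "jzs": "s", "minbf": "D",
}


def _marker(criterion: str) -> str:
    for prefix, marker in _MARKERS.items():
        if criterion.startswith(prefix):
            return marker
    return "."


def tpr_fpr_scatter(rates: pd.DataFrame, out_path: str | Path,
                    title: str = "") -> None:
    """One panel per n_per_arm; symbol = criterion family, colour = Delta."""
    ns = sorted(rates["n_per_arm"].unique())
    fig, axes = plt.subplots(1, len(ns), figsize=(4 * len(ns), 4),
                             sharex=True, sharey=True, squeeze=False)
    cmap = plt.get_cmap("viridis")
    deltas = sorted(rates["clinical_threshold"].unique())
    colors = {d: cmap(i / max(len(deltas) - 1, 1))
              for i, d in enumerate(deltas)}
    for ax, n in zip(axes[0], ns):
        sub = rates[rates["n_per_arm"] == n]
        for _, row in sub.iterrows():
            ax.scatter(row["fpr"], row["tpr"],
                       marker=_marker(row["criterion"]),
                       color=colors[row["clinical_threshold"]], alpha=0.8)
        ax.set_title(f"n = {n} per arm")
        ax.set_xlabel("false positive rate")
    axes[0][0].set_ylabel("true positive rate")
    handles = [plt.Line2D([], [], linestyle="", marker="o", color=c,
                          label=f"Δ = {d:g}")
               for d, c in colors.items()]
    axes[0][-1].legend(handles=handles, fontsize=8, loc="lower right")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
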