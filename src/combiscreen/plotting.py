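"""Optional figure exports (requires matplotlib, installed via the "plot" extra)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["plot_cr_dr_scatter", "plot_delta_heatmap"]


def _mpl():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        return plt
    except ImportError as exc:  # pragma: no cover - extra not installed
        raise ImportError("plotting requires matplotlib (pip install combiscreen[plot])") from exc


def plot_cr_dr_scatter(
    table: pd.DataFrame, path: str | Path, top_k: int = 3, title: str | None = None
) -> None:
    """CR-vs-DR scatter of a ranking table; top-k candidates highlighted.

    High-orthogonality compounds sit in the upper-left corner (CR -> 0,
    DR -> 1).
    """
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(table["cr"], table["dr"], s=12, c="0.6", label="library")
    head = table.head(top_k)
    ax.scatter(head["cr"], head["dr"], s=40, c="crimson", label=f"top {top_k}")
    for _, row in head.iterrows():
        ax.annotate(row["compound"], (row["cr"], row["dr"]), fontsize=7,
                    xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("concordance ratio (CR)")
    ax.set_ylabel("disease discordance ratio (DR)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_delta_heatmap(
    delta: np.ndarray,
    doses_a: np.ndarray,
    doses_b: np.ndarray,
    path: str | Path,
    title: str | None = None,
) -> None:
    """Diverging heat map of a synergy delta surface (red synergy, green antagonism)."""
    plt = _mpl()
    lim = max(1.0, float(np.abs(delta).max()))
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(delta, cmap="PiYG_r", vmin=-lim, vmax=lim, origin="lower")
    ax.set_xticks(range(len(doses_b)), [f"{d:g}" for d in doses_b], fontsize=7)
    ax.set_yticks(range(len(doses_a)), [f"{d:g}" for d in doses_a], fontsize=7)
    ax.set_xlabel("dose of drug B")
    ax.set_ylabel("dose of drug A")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="delta (percentage points)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
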