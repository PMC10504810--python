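"""Plot artifacts: MIP bar charts and pairwise-difference heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def mip_barplot(mips: pd.Series, path: str | Path, threshold: float = 0.5) -> None:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    order = mips.sort_values(ascending=False)
    ax.bar(range(len(order)), order.to_numpy(), color="steelblue")
    ax.axhline(threshold, color="firebrick", linestyle="--", linewidth=1)
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(order.index, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("marginal inclusion probability")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pairwise_heatmap(matrix: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(matrix.to_numpy(), vmin=0, vmax=100, cmap="viridis")
    ax.set_xticks(range(len(matrix.columns)))
    ax.set_xticklabels(matrix.columns, rotation=60, ha="right", fontsize=7)
    ax.set_yticks(range(len(matrix.index)))
    ax.set_yticklabels(matrix.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="% of runs significantly different")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
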