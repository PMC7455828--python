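"""Plain plot exports (volcano, OOB sweep, ROC). PNG/SVG via matplotlib."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def volcano_plot(deg_table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = deg_table["status"].map({"up": "tab:red", "down": "tab:blue", "stable": "0.7"})
    ax.scatter(deg_table["logFC"], -np.log10(deg_table["p"]), s=4, c=colors, linewidths=0)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def sweep_plot(sweep: list[tuple[int, float]], xlabel: str, path: str | Path) -> Path:
    path = Path(path)
    xs, ys = zip(*sweep)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(xs, ys, lw=0.8)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("OOB error")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def roc_plot(results, path: str | Path) -> Path:
    path = Path(path)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for r in results:
        pts = r.points.sort_values("threshold", ascending=False)
        ax.plot(1 - pts["specificity"], pts["sensitivity"], label=f"{r.model_name} (AUC {r.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", c="0.6", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
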