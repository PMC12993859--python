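"""Report figures: detection heatmaps and facility-scale energy charts."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def detection_heatmap(report: pd.DataFrame, treated: str | None = None,
                      path: str | Path | None = None):
    """Net detection rate heatmap, features x window lengths.

    ``report`` is the window-sweep table; when it covers several treated
    groups, ``treated`` selects one (default: the last, i.e. the most
    depleted under the usual naming).
    """
    treated = treated or sorted(report["treated"].unique())[-1]
    sub = report[report["treated"] == treated]
    grid = sub.pivot(index="feature", columns="window_length", values="net_rate")
    fig, ax = plt.subplots(figsize=(0.5 * grid.shape[1] + 2, 0.5 * grid.shape[0] + 1.5))
    im = ax.imshow(grid.to_numpy(), vmin=-1, vmax=1, cmap="RdYlGn", aspect="auto")
    ax.set_xticks(range(grid.shape[1]), grid.columns)
    ax.set_yticks(range(grid.shape[0]), grid.index)
    ax.set_xlabel("window length (days from 4 DAT)")
    ax.set_title(f"net detection rate, {treated} vs control")
    fig.colorbar(im, ax=ax, label="true - false rate")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def energy_bar_chart(report: pd.DataFrame, embodied_kwh: float | None = None,
                     log: bool = True, path: str | Path | None = None):
    """Monthly facility energy per model, optionally against embodied wasted-N.

    ``report`` is the energy_report table (index = model, column
    ``total_Wh``); a log y-axis keeps the ~2000x spread between tiers and
    the embodied-N bar visible on one chart.
    """
    labels = list(report.index)
    values = list(report["total_Wh"])
    if embodied_kwh is not None:
        labels.append("wasted-N embodied")
        values.append(embodied_kwh * 1000.0)
    fig, ax = plt.subplots(figsize=(1.2 * len(labels) + 2, 4))
    colors = ["#4c72b0"] * len(report) + (["#c44e52"] if embodied_kwh else [])
    ax.bar(np.arange(len(labels)), values, color=colors)
    if log:
        ax.set_yscale("log")
    ax.set_xticks(range(len(labels)), labels, rotation=20, ha="right")
    ax.set_ylabel("energy over 28 days x 10,000 heads (Wh)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
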