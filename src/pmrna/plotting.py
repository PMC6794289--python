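"""Minimal figures: MD (mean-difference) plots and marker Z-score timelines."""

from __future__ import annotations

import pandas as pd

_STATUS_COLORS = {"preserved": "#d62728", "degraded": "#1f77b4", "not_de": "0.7"}


def md_plot(md_data: pd.DataFrame, ax=None, title: str | None = None):
    """Scatter logFC against mean logCPM, coloured by preserved/degraded status."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for status, color in _STATUS_COLORS.items():
        sub = md_data[md_data["status"] == status]
        ax.scatter(sub["logCPM"], sub["logFC"], s=4, c=color, label=status,
                   rasterized=True)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("mean log2 CPM")
    ax.set_ylabel("log2 fold change vs 0 h")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, markerscale=3)
    return ax


def z_timeline_plot(timelines, gene_ids=None, ax=None):
    """Plot Z-score trajectories over post-mortem hours for selected genes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    z = timelines.z if gene_ids is None else timelines.z.loc[list(gene_ids)]
    hours = timelines.timepoints
    for gene, row in z.iterrows():
        ax.plot(hours, row.to_numpy(), marker="o", ms=3, lw=1, label=str(gene))
    ax.set_xlabel("post-mortem interval (h)")
    ax.set_ylabel("Z score of mean log2 CPM")
    if len(z) <= 20:
        ax.legend(frameon=False, fontsize=7)
    return ax
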