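"""Per-chromosome scatter of iHS or piHS scores."""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_scores"]


def plot_scores(table: pd.DataFrame, ax=None, kind: str = "pihs", sig_line: float = 5.0):
    """Manhattan-style scatter of ``ihs`` or ``pihs`` by position.

    Chromosomes are laid out side by side in alternating shades; for
    ``kind="pihs"`` a dashed line marks the significance cutoff.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if kind not in ("ihs", "pihs"):
        raise ValueError("kind must be 'ihs' or 'pihs'")
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    t = table[table["valid"]] if "valid" in table else table
    offset = 0
    ticks, labels = [], []
    for k, (chrom, sub) in enumerate(t.groupby("chrom", sort=True)):
        x = sub["pos"].to_numpy() + offset
        ax.scatter(x, sub[kind], s=4, color=("#34618d", "#97a431")[k % 2], rasterized=True)
        ticks.append(offset + sub["pos"].max() / 2)
        labels.append(str(chrom))
        offset += sub["pos"].max() + 1
    if kind == "pihs" and sig_line is not None:
        ax.axhline(sig_line, linestyle="--", color="0.3", linewidth=0.8)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("piHS" if kind == "pihs" else "iHS")
    return ax
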