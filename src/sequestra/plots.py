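"""Manhattan and QQ plots for the association stage (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["manhattan_plot", "qq_plot"]


def manhattan_plot(manhattan_table, bonferroni: float, path) -> None:
    """Save a Manhattan plot; the red line is the Bonferroni threshold."""
    import numpy as np

    fig, ax = plt.subplots(figsize=(9, 3.5))
    chroms = manhattan_table["chrom"].unique()
    for i, chrom in enumerate(chroms):
        sub = manhattan_table[manhattan_table["chrom"] == chrom]
        ax.scatter(sub["genome_pos"], sub["neglog10_p"], s=6,
                   color="C0" if i % 2 == 0 else "C1", linewidths=0)
    ax.axhline(-np.log10(bonferroni), color="red", lw=1)
    ax.set_xlabel("genome position")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_xticks(
        [manhattan_table[manhattan_table["chrom"] == c]["genome_pos"].median()
         for c in chroms],
        labels=list(chroms), rotation=90, fontsize=7,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def qq_plot(qq_table, path) -> None:
    """Save a QQ plot of observed vs expected -log10 p."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(qq_table["expected"], qq_table["observed"], s=6, linewidths=0)
    lim = max(qq_table["expected"].max(), qq_table["observed"].max()) * 1.05
    ax.plot([0, lim], [0, lim], color="grey", lw=1)
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
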