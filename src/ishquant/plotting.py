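"""Publication-style figures: score histograms and percent-positive charts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .stats import PopulationSummary  # noqa: E402

_COLORS = ("#2ca02c", "#d62728", "#9467bd", "#1f77b4")


def plot_score_histograms(summary: PopulationSummary, path=None):
    """Overlaid relative-frequency distributions of the expression score."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for color, (name, pop) in zip(_COLORS, summary.populations.items()):
        h = pop.histogram
        ax.stairs(h.relative_frequency, h.bin_edges, color=color, lw=1.5,
                  label=f"{name} (n={h.n})")
    unit = "dots / 100 µm²" if summary.score_mode == "density" else "dots / cell"
    ax.set_xlabel(f"{summary.target_channel} expression score ({unit})")
    ax.set_ylabel("relative frequency")
    ax.set_title(f"{summary.region_label}: p = {summary.rank_sum.p_two_sided:.3g} "
                 f"(rank-sum, two-sided)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_percent_positive(summary: PopulationSummary, path=None):
    """Pie charts of percent target-positive cells per population."""
    pops = list(summary.populations.items())
    fig, axes = plt.subplots(1, len(pops), figsize=(3.2 * len(pops), 3.2))
    if len(pops) == 1:
        axes = [axes]
    for ax, color, (name, pop) in zip(axes, _COLORS, pops):
        pct = pop.percent_positive.pooled
        ax.pie([pct, 100 - pct], colors=[color, "#dddddd"],
               startangle=90, counterclock=False,
               wedgeprops={"edgecolor": "white"})
        ax.set_title(f"{name}\n{pct:.1f}% {summary.target_channel}+", fontsize=10)
    fig.suptitle(summary.region_label)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
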