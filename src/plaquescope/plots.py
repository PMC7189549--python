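"""Figure helpers: grouped-score boxplots and FOV overview images.

Conventions follow the field's reporting style: boxplot whiskers at
+/- 1.5 IQR, outliers as red '+', medians as red lines, significance
stars drawn between group pairs.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cohort_stats import significance_stars


def boxplot_scores_by_group(scores_by_group, title="", ylabel="CNN score",
                            pair_pvalues=None, path=None):
    """Boxplot of score distributions per group.

    ``pair_pvalues``: optional list of ``(group1, group2, p)`` to annotate
    with significance stars (pairs with no stars are skipped).
    Returns the matplotlib figure; saves to ``path`` if given.
    """
    names = list(scores_by_group)
    data = [np.asarray(scores_by_group[g], dtype=float) for g in names]
    fig, ax = plt.subplots(figsize=(1.6 * len(names) + 1.5, 3.6))
    ax.boxplot(
        data,
        tick_labels=names,
        whis=1.5,
        sym="r+",
        medianprops={"color": "red"},
    )
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    if pair_pvalues:
        top = max((d.max() for d in data if len(d)), default=1.0)
        step = 0.08 * (top if top > 0 else 1.0)
        height = top + step
        index = {g: i + 1 for i, g in enumerate(names)}
        for g1, g2, p in pair_pvalues:
            stars = significance_stars(p)
            if not stars:
                continue
            x1, x2 = index[g1], index[g2]
            ax.plot([x1, x1, x2, x2], [height, height + step / 3, height + step / 3, height],
                    color="black", linewidth=1)
            ax.text((x1 + x2) / 2, height + step / 3, stars, ha="center", va="bottom")
            height += step
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def fov_overview_image(heatmap_channel, windows, path=None, cmap="magma"):
    """Render a heatmap with the selected FOV windows as numbered boxes.

    ``windows`` is an ordered list of FOVWindow (highest score first, as
    returned by the top-n selection).  Returns the figure; saves to
    ``path`` if given.
    """
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(np.asarray(heatmap_channel), cmap=cmap, interpolation="nearest")
    for rank, fw in enumerate(windows, start=1):
        ax.add_patch(
            plt.Rectangle(
                (fw.col, fw.row), fw.window_size, fw.window_size,
                fill=False, edgecolor="white", linewidth=1.5,
            )
        )
        ax.text(fw.col + 2, fw.row + 2, str(rank), color="white",
                ha="left", va="top", fontsize=10, fontweight="bold")
    ax.set_axis_off()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
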