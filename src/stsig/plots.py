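"""Array-overlay plots: spots drawn at (x, -y), one panel per section."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

_PALETTE = ("#2ca02c", "#1f77b4", "#ff7f0e", "#7f7f7f", "#d62728")


def spot_overlay(values: pd.Series, path, title: str | None = None) -> None:
    """Scatter spots colored by a categorical value, one panel per dataset.

    ``values`` is a Series over (dataset, x, y) spot keys holding group or
    class assignments.
    """
    datasets = list(dict.fromkeys(values.index.get_level_values(0)))
    cats = list(dict.fromkeys(values))
    colors = {c: _PALETTE[i % len(_PALETTE)] for i, c in enumerate(cats)}
    fig, axes = plt.subplots(1, len(datasets),
                             figsize=(4 * len(datasets), 4), squeeze=False)
    for ax, ds in zip(axes[0], datasets):
        sub = values[values.index.get_level_values(0) == ds]
        xs = sub.index.get_level_values(1)
        ys = sub.index.get_level_values(2)
        ax.scatter(xs, -ys, c=[colors[v] for v in sub], s=12, linewidths=0)
        ax.set_title(str(ds))
        ax.set_aspect("equal")
        ax.set_xticks([])
        ax.set_yticks([])
    handles = [plt.Line2D([], [], marker="o", linestyle="", color=colors[c],
                          label=str(c)) for c in cats]
    fig.legend(handles=handles, loc="lower center", ncol=len(cats),
               frameon=False)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
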