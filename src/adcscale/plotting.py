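"""Prediction-ratio plots.

Two figures mirror the headline comparisons of the analysis: three-species
simple allometry vs the Rule of Exponents, and mouse one-species scaling
with exponent 1.0 vs the exponent-averaging strategy.  A ratio of 1 means
no prediction error; the dashed lines mark the 0.5–2-fold acceptance band.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .allometry import HumanPrediction

__all__ = ["plot_ratio_comparison"]


def plot_ratio_comparison(
    groups: dict[str, Sequence[HumanPrediction]],
    title: str = "Predicted/observed human clearance",
    ax: "plt.Axes | None" = None,
) -> "plt.Axes":
    """Scatter prediction ratios for one or more strategies side by side.

    ``groups`` maps a legend label to evaluated predictions (ratio filled).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    markers = ["o", "s", "^", "d", "v"]
    for i, (label, preds) in enumerate(groups.items()):
        xs, ys = [], []
        for p in preds:
            if p.ratio is None:
                continue
            xs.append(f"{p.drug}\n({p.analyte})")
            ys.append(p.ratio)
        ax.scatter(xs, ys, label=label, marker=markers[i % len(markers)], alpha=0.8)
    ax.axhline(1.0, color="k", lw=0.8)
    ax.axhline(0.5, color="gray", ls="--", lw=0.8)
    ax.axhline(2.0, color="gray", ls="--", lw=0.8)
    ax.set_ylabel("prediction ratio (predicted / observed)")
    ax.set_yscale("log")
    ax.set_title(title)
    ax.legend()
    ax.tick_params(axis="x", rotation=75, labelsize=7)
    if ax.figure is not None:
        ax.figure.tight_layout()
    return ax
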