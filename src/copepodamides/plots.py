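"""Figure helpers: ordination with centroids/ellipses, stacked composition
bars, and content-vs-mass scatter on log axes.

Matplotlib is imported lazily and the Agg backend is safe; every function
returns the Figure so callers can save or embed it.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ordination_plot", "composition_bars", "content_scatter"]

_HABITAT_COLOURS = {"freshwater": "tab:green", "marine": "tab:blue"}


def _colour(group: str, index: int):
    import matplotlib.pyplot as plt

    return _HABITAT_COLOURS.get(str(group), plt.get_cmap("tab10")(index % 10))


def ordination_plot(coords: pd.DataFrame, groups: Sequence, level: float = 0.95):
    """nMDS ordination with group centroids and centroid confidence ellipses."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse as MplEllipse

    from .stats import Ellipse, centroid_ellipses

    fig, ax = plt.subplots(figsize=(5, 4))
    labels = np.asarray(groups)
    ellipses = centroid_ellipses(coords, labels, level=level)
    for i, g in enumerate(pd.unique(labels)):
        pts = coords.to_numpy()[labels == g]
        colour = _colour(g, i)
        ax.scatter(pts[:, 0], pts[:, 1], s=18, alpha=0.6, color=colour, label=str(g))
        ell = ellipses[str(g)]
        if isinstance(ell, Ellipse):
            ax.scatter(*ell.center, s=90, color=colour, edgecolor="black", zorder=3)
            ax.add_patch(
                MplEllipse(
                    ell.center, 2 * ell.semi_axes[0], 2 * ell.semi_axes[1],
                    angle=ell.angle_deg, facecolor=colour, alpha=0.2,
                    edgecolor=colour,
                )
            )
    ax.set_xlabel("nMDS1")
    ax.set_ylabel("nMDS2")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def composition_bars(composition: pd.DataFrame, groups: Mapping[str, str] | None = None):
    """Stacked relative-abundance bars, one bar per sample.

    CA species are drawn in blues, dhCA species in greens, mirroring the
    scaffold split the habitat comparison turns on.
    """
    import matplotlib.pyplot as plt

    rel = composition.div(composition.sum(axis=1), axis=0).fillna(0.0)
    ca_cols = [c for c in rel.columns if c.endswith(" CA")]
    dhca_cols = [c for c in rel.columns if c.endswith(" dhCA")]
    ordered = ca_cols + dhca_cols + [c for c in rel.columns if c not in ca_cols + dhca_cols]
    rel = rel[ordered]

    blues = plt.get_cmap("Blues")
    greens = plt.get_cmap("Greens")
    colours = []
    for c in ordered:
        if c in ca_cols:
            colours.append(blues(0.3 + 0.6 * ca_cols.index(c) / max(1, len(ca_cols))))
        elif c in dhca_cols:
            colours.append(greens(0.3 + 0.6 * dhca_cols.index(c) / max(1, len(dhca_cols))))
        else:
            colours.append("0.6")

    fig, ax = plt.subplots(figsize=(max(5, 0.35 * len(rel)), 4))
    bottom = np.zeros(len(rel))
    for c, colour in zip(ordered, colours):
        ax.bar(range(len(rel)), rel[c], bottom=bottom, color=colour, width=0.85,
               label=c)
        bottom += rel[c].to_numpy()
    ax.set_xticks(range(len(rel)))
    ax.set_xticklabels(rel.index, rotation=90, fontsize=7)
    ax.set_ylabel("relative abundance")
    ax.legend(frameon=False, fontsize=6, ncol=2, bbox_to_anchor=(1.02, 1),
              loc="upper left")
    fig.tight_layout()
    return fig


def content_scatter(quant: pd.DataFrame):
    """Total copepodamide content (pmol per individual) against estimated dry
    mass (ug), per habitat, on ln-ln axes with the fitted regressions."""
    import matplotlib.pyplot as plt

    from .quant import allometric_regression

    fig, ax = plt.subplots(figsize=(5, 4))
    for i, (habitat, sub) in enumerate(quant.groupby("habitat")):
        colour = _colour(habitat, i)
        ok = (sub["total_pmol"] > 0) & (sub["dry_mass_ug"] > 0)
        sub = sub[ok]
        ax.scatter(sub["dry_mass_ug"], sub["total_pmol"], s=16, alpha=0.6,
                   color=colour, label=str(habitat))
        if ok.sum() >= 3:
            fit = allometric_regression(sub["total_pmol"], sub["dry_mass_ug"])
            xs = np.linspace(np.log(sub["dry_mass_ug"].min()),
                             np.log(sub["dry_mass_ug"].max()), 50)
            ax.plot(np.exp(xs), np.exp(fit.intercept + fit.slope * xs),
                    color=colour, lw=2)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("dry mass (µg)")
    ax.set_ylabel("total copepodamides (pmol ind$^{-1}$)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig
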