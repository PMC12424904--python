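"""Cumulative-incidence figure helpers."""

from __future__ import annotations

from typing import Mapping, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .lifetime_risk import CifCurve


def plot_cif_curves(
    curves: Mapping[str, CifCurve],
    ax: Optional[plt.Axes] = None,
    title: str = "",
    percent: bool = True,
):
    """Plot PGS-stratum cumulative incidence curves with bootstrap bands.

    One line per stratum; shaded 95% bands where present.  Returns the axes.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    scale = 100.0 if percent else 1.0
    for label, curve in curves.items():
        (line,) = ax.plot(curve.age_grid, scale * curve.cif, label=label)
        if curve.ci_low is not None and curve.ci_high is not None:
            ax.fill_between(
                curve.age_grid,
                scale * curve.ci_low,
                scale * curve.ci_high,
                alpha=0.2,
                color=line.get_color(),
                linewidth=0,
            )
    ax.set_xlabel("Age (years)")
    ax.set_ylabel("Cumulative incidence (%)" if percent else "Cumulative incidence")
    if title:
        ax.set_title(title)
    ax.legend(title="PGS group", fontsize=8)
    return ax
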