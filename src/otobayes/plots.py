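"""Optional, side-effect-free plot export (matplotlib Agg backend)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .survey import SurveyDataset

__all__ = ["plot_min_age_distribution", "plot_posterior_density"]


def plot_min_age_distribution(dataset: SurveyDataset, path: str | Path) -> None:
    """Violin-plus-box plot of numeric minimum-age responses."""
    ages = [r.min_age_years for r in dataset if r.min_age_kind == "numeric"]
    fig, ax = plt.subplots(figsize=(4, 5))
    if ages:
        ax.violinplot(ages, showextrema=False)
        ax.boxplot(ages, widths=0.1)
    ax.set_ylabel("reported minimum age (years)")
    ax.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_posterior_density(
    draw_sets: Sequence[np.ndarray],
    labels: Sequence[str],
    path: str | Path,
    xlabel: str = "probability of opioid-sparing prescribing",
) -> None:
    """Overlaid histogram-density of posterior probability draws."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for draws, label in zip(draw_sets, labels):
        ax.hist(np.asarray(draws, float), bins=60, density=True,
                histtype="step", label=label)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("posterior density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
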