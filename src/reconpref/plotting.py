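"""Median/IQR figures for the three instruments.

These mirror the study's presentation: per-option-group medians with
interquartile bars for the VAS (with and without death) and the chained
standard-gamble utilities, plus implant/tissue ratings split by BMI
category.
"""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

_MEASURE_LABELS = {
    "rank": "Card ranking (1 = most preferred)",
    "vas": "VAS, without death (0-100)",
    "vas_death": "VAS, with death (0-100)",
    "utility": "Standard-gamble utility (0-1)",
}


def _errbars(summary: pd.DataFrame, measure: str):
    med = summary[f"{measure}_median"].to_numpy(float)
    lo = med - summary[f"{measure}_q1"].to_numpy(float)
    hi = summary[f"{measure}_q3"].to_numpy(float) - med
    return med, np.vstack([lo, hi])


def plot_instrument_medians(
    summary: pd.DataFrame,
    measures: tuple[str, ...] = ("vas", "vas_death", "utility"),
    fig: Optional[plt.Figure] = None,
) -> plt.Figure:
    """Medians with IQR bars per (option group, quality) row, one panel per
    instrument."""
    if fig is None:
        fig, axes = plt.subplots(1, len(measures), figsize=(5 * len(measures), 4.5),
                                 sharey=False)
    else:
        axes = fig.subplots(1, len(measures))
    if len(measures) == 1:
        axes = [axes]
    labels = [f"{g}/{q}" for g, q in summary.index]
    x = np.arange(len(labels))
    for ax, measure in zip(np.atleast_1d(axes), measures):
        med, err = _errbars(summary, measure)
        ok = np.isfinite(med)
        ax.errorbar(x[ok], med[ok], yerr=err[:, ok], fmt="o", capsize=3)
        ax.set_xticks(x)
        ax.set_xticklabels(labels, rotation=75, fontsize=7)
        ax.set_title(_MEASURE_LABELS.get(measure, measure), fontsize=9)
        ax.grid(alpha=0.3)
    fig.tight_layout()
    return fig


def plot_bmi_ratings(
    ratings: pd.DataFrame, covariates: pd.DataFrame, include_death: bool = False
) -> plt.Figure:
    """Implant and tissue VAS medians with IQR bars by BMI category."""
    from .study import group_scores, _wide

    mask = ratings["include_death"].astype(bool) == include_death
    wide = _wide(ratings[mask], "rating")
    bmi = covariates.set_index("participant_id")["bmi_category"].astype(str)
    cats = ["normal", "overweight", "obese"]
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, group in zip(axes, ("implant", "tissue")):
        scores = group_scores(wide, group).dropna()
        med, lo, hi = [], [], []
        for cat in cats:
            vals = scores[bmi.reindex(scores.index) == cat]
            if len(vals):
                q1, q2, q3 = np.percentile(vals, [25, 50, 75])
            else:
                q1 = q2 = q3 = np.nan
            med.append(q2); lo.append(q2 - q1); hi.append(q3 - q2)
        x = np.arange(len(cats))
        ax.errorbar(x, med, yerr=np.vstack([lo, hi]), fmt="s", capsize=4)
        ax.set_xticks(x)
        ax.set_xticklabels(cats)
        ax.set_title(f"{group}-based reconstruction")
        ax.grid(alpha=0.3)
    axes[0].set_ylabel("VAS rating")
    fig.tight_layout()
    return fig
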