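"""Bar-chart summaries of unrest and permanence per treatment cell."""

from __future__ import annotations

from typing import Mapping

import pandas as pd

_TEMP_ORDER = ["cold", "neutral", "hot"]
_LIGHT_ORDER = ["white", "green", "red"]
_LIGHT_COLORS = {"white": "#c9c9c9", "green": "#4daf4a", "red": "#e41a1c"}


def plot_unrest(agg: pd.DataFrame, letters: Mapping[tuple[str, str], str] | None = None, ax=None):
    """Grouped bars of mean unrest per (temperature, light), SD whiskers.

    ``letters`` optionally maps (light, temperature) to a compact letter
    display drawn above each bar.
    """
    return _grouped_bars(agg, "mean_unrest_px", "Unrest index (px)", letters, ax, yerr_col="sd")


def plot_permanence(perm: pd.DataFrame, letters=None, ax=None):
    """Grouped bars of cumulative permanence time (hours) per treatment."""
    return _grouped_bars(perm, "T_bird_hours", "Permanence time (bird-hours)", letters, ax)


def _grouped_bars(df, value_col, ylabel, letters, ax, yerr_col=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    temps = [t for t in _TEMP_ORDER if t in set(df["temperature"])]
    lights = [l for l in _LIGHT_ORDER if l in set(df["light"])]
    width = 0.8 / max(len(lights), 1)
    for j, light in enumerate(lights):
        xs, ys, errs = [], [], []
        for i, temp in enumerate(temps):
            row = df[(df["light"] == light) & (df["temperature"] == temp)]
            if row.empty:
                continue
            x = i + (j - (len(lights) - 1) / 2) * width
            y = float(row[value_col].iloc[0])
            xs.append(x)
            ys.append(y)
            errs.append(float(row[yerr_col].iloc[0]) if yerr_col else 0.0)
            if letters:
                ax.text(x, y, letters.get((light, temp), ""), ha="center", va="bottom")
        ax.bar(xs, ys, width=width * 0.9, yerr=errs if yerr_col else None,
               label=light, color=_LIGHT_COLORS.get(light), edgecolor="black", capsize=3)
    ax.set_xticks(range(len(temps)))
    ax.set_xticklabels(temps)
    ax.set_ylabel(ylabel)
    ax.legend(title="light")
    return ax
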