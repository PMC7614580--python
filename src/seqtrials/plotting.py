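"""Figure helpers: survival-curve panels and weight diagnostics.

Thin matplotlib wrappers over the curve and diagnostic exports; every
function accepts an existing Axes so panels compose into larger figures.
"""

from __future__ import annotations

import numpy as np


def plot_survival_curves(curves, truth=None, ax=None, title=None):
    """Overlay counterfactual survival curves (optionally with the truth).

    ``curves`` is an iterable of SurvivalCurve; ``truth`` an optional
    TruthCurves object drawn as dashed reference lines.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for c in curves:
        ax.step(c.times, c.S, where="post", label=c.regime)
    if truth is not None:
        ax.plot(truth.times, truth.S1, "k--", lw=1, label="truth (always)")
        ax.plot(truth.times, truth.S0, "k:", lw=1, label="truth (never)")
    ax.set_xlabel("time since baseline")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend()
    return ax


def plot_risk_difference(rd, ci=None, ax=None, title=None):
    """Risk-difference curve with optional bootstrap interval band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.step(rd.times, rd.RD, where="post", color="C0")
    if ci is not None:
        ax.fill_between(ci.taus, ci.lower["RD"], ci.upper["RD"],
                        step="post", alpha=0.25, color="C0")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("time since baseline")
    ax.set_ylabel("risk difference (always - never)")
    if title:
        ax.set_title(title)
    return ax


def plot_max_weights(max_weights, ax=None, log=True):
    """Per-replicate maximum weight by period, one box per method."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    methods = sorted(max_weights["method"].unique())
    periods = sorted(max_weights["period"].unique())
    width = 0.8 / len(methods)
    for i, m in enumerate(methods):
        sub = max_weights[max_weights["method"] == m]
        data = [sub.loc[sub["period"] == p, "max_weight"].to_numpy()
                for p in periods]
        pos = np.array(periods) + (i - (len(methods) - 1) / 2) * width
        bp = ax.boxplot(data, positions=pos, widths=width * 0.9,
                        patch_artist=True)
        for box in bp["boxes"]:
            box.set_facecolor(f"C{i}")
            box.set_alpha(0.6)
        ax.plot([], [], color=f"C{i}", label=m)
    if log:
        ax.set_yscale("log")
    ax.set_xticks(periods)
    ax.set_xticklabels(periods)
    ax.set_xlabel("time period")
    ax.set_ylabel("largest weight per replicate")
    ax.legend()
    return ax
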