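"""Plot helpers: fitted hormetic curve with shaded zones, simple-slope
curves, and Johnson-Neyman significance plots."""

from __future__ import annotations

import numpy as np

from .curve import HormesisProfile
from .moderation import JNResult

_REGION_COLORS = {
    "strengthening": "#74add1",
    "buffering": "#abd9e9",
    "rising_toxic": "#fdae61",
    "falling_toxic": "#d73027",
}


def plot_hormesis_profile(profile: HormesisProfile, ax=None, x_range=(-3.0, 3.0)):
    """Fitted cubic with the four regions shaded and breakpoints marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.2))
    lo, hi = x_range
    x = np.linspace(lo, hi, 400)
    ax.plot(x, profile.curve(x), color="black", lw=2)
    hv, ci, tv = profile.region_bounds
    edges = [lo, hv, ci, tv, hi]
    for (a, b), name in zip(zip(edges[:-1], edges[1:]), _REGION_COLORS):
        ax.axvspan(a, b, color=_REGION_COLORS[name], alpha=0.35, label=name.replace("_", " "))
    for v, ls in ((hv, ":"), (ci, "--"), (tv, ":")):
        ax.axvline(v, color="gray", ls=ls, lw=1)
    ax.set_xlabel("adversity (centered factor score)")
    ax.set_ylabel("predicted symptom change")
    ax.legend(loc="upper left", fontsize=8)
    return ax


def plot_simple_slopes(curves: dict, ax=None):
    """Curves from :func:`hormesis.moderation.simple_slope_curves`."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.2))
    for w, data in sorted(curves.items()):
        ax.plot(data["x"], data["y"], label=f"moderator = {w:+.2g}")
    ax.set_xlabel("adversity (centered factor score)")
    ax.set_ylabel("predicted symptom change")
    ax.legend(fontsize=8)
    return ax


def plot_johnson_neyman(jn: JNResult, w_range=(-3.0, 3.0), ax=None):
    """Conditional effect with confidence band; significant moderator ranges shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.2))
    w = np.linspace(*w_range, 400)
    theta = jn.theta(w)
    half = jn.t_crit * np.sqrt(jn.var_theta(w))
    ax.plot(w, theta, color="black")
    ax.fill_between(w, theta - half, theta + half, color="gray", alpha=0.3)
    ax.axhline(0, color="red", lw=1)
    for lo, hi, sig, _ in jn.intervals:
        if sig:
            ax.axvspan(max(lo, w_range[0]), min(hi, w_range[1]), color="#1a9850", alpha=0.2)
    for b in jn.boundaries:
        ax.axvline(b, color="#1a9850", ls="--", lw=1)
    ax.set_xlabel("moderator")
    ax.set_ylabel(f"conditional effect ({jn.effect})")
    return ax
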