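"""Optional Bland-Altman plot (bias, limits of agreement, trend line)."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .evaluation import BlandAltmanResult, PairedSeries, bland_altman


def bland_altman_plot(
    pairs: PairedSeries,
    result: Optional[BlandAltmanResult] = None,
    ax=None,
    title: Optional[str] = None,
):
    """Scatter of differences against pairwise means with bias (black),
    limits of agreement (red) and the fitted trend line; points colored
    per subject.  Returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if result is None:
        result = bland_altman(pairs)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    d = pairs.estimate - pairs.reference
    m = (pairs.estimate + pairs.reference) / 2.0
    for s in np.unique(pairs.subject):
        mask = pairs.subject == s
        ax.scatter(m[mask], d[mask], s=8, alpha=0.6, label=str(s))
    ax.axhline(result.bias_mm, color="black", lw=1.2)
    ax.axhline(result.loa_lower_mm, color="red", lw=1.0, ls="--")
    ax.axhline(result.loa_upper_mm, color="red", lw=1.0, ls="--")
    xs = np.array([m.min(), m.max()])
    ax.plot(xs, result.slope * xs + result.intercept_mm, color="tab:blue", lw=1.0)
    ax.set_xlabel(f"mean of estimate and reference ({pairs.axis}, mm)")
    ax.set_ylabel("difference (mm)")
    if title:
        ax.set_title(title)
    return ax
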