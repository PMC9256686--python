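"""Simple diagnostic figures.

Matplotlib is imported lazily so headless library use never touches a
display backend.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_connectivity_scatter(m1, shc, estimate=None, ax=None):
    """M1 vs SHc points with the fitted effective-connectivity line."""
    ax = _axes(ax)
    m1 = np.asarray(m1, dtype=float)
    ax.scatter(m1, np.asarray(shc, dtype=float), color="k", s=20)
    if estimate is not None:
        xs = np.linspace(m1.min(), m1.max(), 50)
        ax.plot(xs, estimate.intercept + estimate.slope * xs, color="tab:red",
                label=f"slope = {estimate.slope:.2f}, r = {estimate.r:.2f}")
        ax.legend(frameon=False)
    ax.set_xlabel("M1 activity (z)")
    ax.set_ylabel("SHc activity (z)")
    return ax


def plot_weights_vs_ehi(weights: pd.DataFrame, metadata: pd.DataFrame,
                        hand: str, term: str = "w_direct_contra", ax=None):
    """Scatter of one weight term against the EHI score."""
    ax = _axes(ax)
    sub = weights[weights.hand == hand].set_index("participant_id")
    ehi = metadata.set_index("participant_id")["ehi"]
    common = sub.index.intersection(ehi.index)
    ax.scatter(sub.loc[common, term], ehi.loc[common], color="k", s=25)
    ax.set_xlabel(f"{term} ({hand})")
    ax.set_ylabel("EHI score")
    return ax


def plot_bootstrap_null(comparison, ax=None, bins: int = 40):
    """Null ΔR² histogram with the observed value and the 95% band."""
    ax = _axes(ax)
    ax.hist(comparison.null_delta, bins=bins, color="0.7")
    for x, style in ((comparison.ci_low, ":"), (comparison.ci_high, ":")):
        ax.axvline(x, color="k", linestyle=style)
    ax.axvline(comparison.observed_delta, color="tab:red",
               label=f"observed δ = {comparison.observed_delta:.3f}")
    ax.set_xlabel("ΔR² under the swap null")
    ax.legend(frameon=False)
    return ax
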