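"""Minimal plotting helpers: scatter with model fits, LOO forest, funnel.

These render the exported figure data; styling is deliberately plain.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .io import HarmonizedSet  # noqa: E402


def scatter_plot(h: HarmonizedSet, results, ax=None):
    """SNP-exposure vs SNP-outcome effects with one fitted line per model."""
    ax = ax or plt.gca()
    sign = np.where(h.gamma < 0, -1.0, 1.0)
    g, G = h.gamma * sign, h.Gamma * sign
    ax.errorbar(g, G, xerr=h.sigma_x, yerr=h.sigma_y, fmt="o", ms=4,
                color="0.3", ecolor="0.7", lw=0.8)
    xs = np.linspace(0, g.max() * 1.05, 50)
    for method, r in results.items():
        b0 = r.extra.get("intercept", 0.0)
        ax.plot(xs, b0 + r.beta * xs, label=method, lw=1.2)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.set_xlabel("SNP effect on exposure (SD)")
    ax.set_ylabel("SNP effect on outcome (log-odds)")
    ax.legend(fontsize=7)
    return ax


def forest_plot(loo_table, full_beta=None, ax=None):
    """Leave-one-out forest: one CI bar per excluded SNP."""
    ax = ax or plt.gca()
    y = np.arange(len(loo_table))[::-1]
    ax.errorbar(loo_table["beta"], y,
                xerr=1.96 * loo_table["se"], fmt="o", ms=3, color="0.2")
    ax.axvline(0, color="red", lw=0.8, ls="--")
    if full_beta is not None:
        ax.axvline(full_beta, color="0.5", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(loo_table["snp_id"], fontsize=7)
    ax.set_xlabel("IVW estimate excluding SNP (log-odds per SD)")
    return ax


def funnel_plot(h: HarmonizedSet, beta=None, ax=None):
    """Per-SNP ratio vs precision; asymmetry hints at directional pleiotropy."""
    ax = ax or plt.gca()
    theta = h.Gamma / h.gamma
    se = h.sigma_y / np.abs(h.gamma)
    ax.plot(theta, 1.0 / se, "o", ms=4, color="0.3")
    if beta is not None:
        ax.axvline(beta, color="red", lw=0.8, ls="--")
    ax.set_xlabel("per-SNP causal ratio")
    ax.set_ylabel("precision (1/SE)")
    return ax
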