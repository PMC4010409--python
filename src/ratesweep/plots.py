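"""Publication-style plots: count histograms with fitted curves, and sweep
panels of marginal likelihood / parameters against the number of gamma
categories."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .count_fit import DistFit, Histogram  # noqa: E402
from .sweep import SweepResult  # noqa: E402

__all__ = ["plot_count_histogram", "plot_sweep"]


def plot_count_histogram(
    hist: Histogram,
    poisson_fit: DistFit | None = None,
    negbin_fit: DistFit | None = None,
    path=None,
    title: str = "",
):
    """Semi-log histogram of sites per substitution count, with fitted
    Poisson (red) and negative-binomial (green) curves."""
    from scipy import stats

    fig, ax = plt.subplots(figsize=(5, 3.5))
    v = np.arange(len(hist.frequencies))
    ax.bar(v, hist.frequencies, color="0.6", width=0.8, label="observed")
    S = hist.total
    if poisson_fit is not None and poisson_fit.ok:
        lam = poisson_fit.params["lam"]
        ax.plot(v, S * stats.poisson.pmf(v, lam), "r-", lw=1.5, label="Poisson")
    if negbin_fit is not None and negbin_fit.ok:
        m, a = negbin_fit.params["m"], negbin_fit.params["alpha"]
        ax.plot(v, S * stats.nbinom.pmf(v, a, a / (a + m)), "g-", lw=1.5,
                label="negative binomial")
    ax.set_yscale("log")
    ax.set_xlabel("substitutions per site")
    ax.set_ylabel("number of sites")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_sweep(sweep: SweepResult, path=None, title: str = ""):
    """Marginal likelihood, alpha, p_inv, rate and root age against k."""
    panels = [
        ("logML", "log marginal likelihood"),
        ("alpha_mean", "gamma shape alpha"),
        ("pinv_mean", "p_inv"),
        ("rate_mean", "substitution rate"),
        ("root_mean", "root age"),
    ]
    fig, axes = plt.subplots(len(panels), 1, figsize=(5, 2.2 * len(panels)),
                             sharex=True)
    kinds = sorted({("gamma_inv" if r["pinv_on"] else "gamma") for r in sweep.rows})
    style = {"gamma": ("o-", "tab:blue"), "gamma_inv": ("s--", "tab:red")}
    for ax, (fld, label) in zip(axes, panels):
        for kind in kinds:
            ks = sweep.k_values(kind)
            ys = sweep.series(fld, kind)
            fmt, col = style.get(kind, ("o-", "k"))
            ax.plot(ks, ys, fmt, color=col, ms=4, label=kind)
        ax.set_ylabel(label, fontsize=8)
    axes[-1].set_xlabel("number of gamma rate categories (k)")
    axes[0].legend(frameon=False, fontsize=8)
    if title:
        axes[0].set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
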