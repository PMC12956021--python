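"""Diagnostic plots for fluctuation results and reversion curves.

matplotlib is imported lazily; install the ``plot`` extra to use this
module.  These are quick-look diagnostics (per-clone survival bars,
passage-vs-passage scatter with the regression line, fitted decay curves),
not publication figures.
"""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_survival_bars(results, passage=None, ax=None):
    """Per-clone survival bars for one passage (sorted descending)."""
    plt = _plt()
    passage = passage or results.model.passages[0]
    vals = np.sort(results.model.survival(passage))[::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.bar(np.arange(vals.size), vals, color="0.5")
    ax.axhline(1.0, ls="--", c="k", lw=0.8)
    ax.set_xlabel("clone (sorted)")
    ax.set_ylabel("survival fraction")
    ax.set_title(
        f"{passage}: mean {results.mean_survival[passage]:.2f}, "
        f"CV {results.cv_[passage]:.3f} ± {results.cv_halfwidth_[passage]:.3f}"
    )
    return ax


def plot_passage_scatter(results, pa=None, pb=None, ax=None):
    """Survival at one passage against another, with the OLS line."""
    plt = _plt()
    if pa is None or pb is None:
        (pa, pb), _ = next(iter(results.correlations_.items()))
    a, b = results.model._paired(pa, pb)
    d = results.correlations_[(pa, pb)]
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(a, b, s=15, c="0.3")
    xs = np.linspace(a.min(), a.max(), 50)
    ax.plot(xs, d["intercept"] + d["slope"] * xs, "r-", lw=1)
    ax.set_xlabel(f"survival {pa}")
    ax.set_ylabel(f"survival {pb}")
    ax.set_title(f"r = {d['r']:+.2f}, p = {d['p']:.2g}")
    return ax


def plot_reversion(fit_results, ax=None):
    """Observed reversion curve with the fitted geometric decay."""
    plt = _plt()
    m = fit_results.model
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(m.generations, m.fraction, "o", c="0.3", label="observed")
    gs = np.linspace(m.generations.min(), m.generations.max(), 100)
    ax.plot(gs, fit_results.predict(gs), "r-", lw=1,
            label=f"fit: k_off={fit_results.k_off:.3f}")
    ax.set_xlabel("generations in attached culture")
    ax.set_ylabel("resistant fraction / survival")
    ax.legend()
    return ax
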