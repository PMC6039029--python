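"""Optional matplotlib convenience plots (requires the `plots` extra)."""

from __future__ import annotations

import math

__all__ = ["plot_production_probabilities", "plot_traces", "plot_coding_fit"]


def _plt():
    try:
        import matplotlib.pyplot as plt
    except ImportError as e:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (pip install geolot[plots])") from e
    return plt


def plot_production_probabilities(summary, ax=None, atomic_only: bool = True):
    """Bar chart of posterior mean +/- SE per production."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3.5))
    df = summary
    if atomic_only:
        df = df.loc[[i for i in df.index if i.startswith("ATOMIC:")]]
    labels = [i.split(":", 1)[1] for i in df.index]
    ax.bar(labels, df["mean"], yerr=df["se"], capsize=2)
    ax.set_ylabel(r"inferred $\theta_i$")
    ax.tick_params(axis="x", rotation=60)
    return ax


def plot_traces(result, production_id: str, ax=None):
    """Per-chain trace of one production's theta across MCMC steps."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots()
    j = result.production_ids.index(production_id)
    for c in range(result.traces.shape[0]):
        ax.plot(result.traces[c, :, j], label=f"chain {c}")
    ax.axvline(result.config.burn_in, ls="--", c="k", lw=0.8)
    ax.set_xlabel("MCMC step")
    ax.set_ylabel(rf"$\theta$[{production_id}]")
    ax.legend(fontsize=8)
    return ax


def plot_coding_fit(fit, ax=None):
    """Mean probability per complexity value with the fitted log-linear line."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots()
    ks = sorted(fit.points)
    means = [fit.points[k][0] for k in ks]
    ax.semilogy(ks, means, "o", label=f"|x| = {fit.length}")
    if fit.defined:
        ys = [10 ** (fit.slope * k + fit.intercept) for k in ks]
        ax.semilogy(ks, ys, "-", label=rf"$R^2$ = {fit.r_squared:.2f}")
    ax.set_xlabel(r"$K_{Geo}(x)$")
    ax.set_ylabel(r"mean $P_{Geo}(x)$")
    ax.legend()
    return ax
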