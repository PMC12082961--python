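"""Optional study-style figures (ensemble traces, band power, baselines).

Matplotlib is imported lazily so headless/statistics-only use never touches
a plotting backend.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_ensemble", "plot_band_power", "plot_baselines"]


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_ensemble(ensembles: dict, path=None):
    """One panel per condition: ensemble mean diameter with SD error bars."""
    plt = _plt()
    fig, axes = plt.subplots(len(ensembles), 1, figsize=(7, 2.6 * len(ensembles)),
                             sharex=True, squeeze=False)
    for ax, (cond, ens) in zip(axes.ravel(), ensembles.items()):
        t = np.arange(len(ens.mean_trace))
        ax.errorbar(t, ens.mean_trace, yerr=ens.sd_trace, lw=1.2,
                    elinewidth=0.5, capsize=1.5, color="tab:blue")
        ax.set_ylabel("diameter (mm)")
        ax.set_title(str(cond))
    axes.ravel()[-1].set_xlabel("time (s)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_band_power(log_power_summary: dict, path=None):
    """Bar chart of mean band log-power per paced condition (error bars: SD)."""
    plt = _plt()
    conds = list(log_power_summary)
    means = [log_power_summary[c]["mean"] for c in conds]
    sds = [log_power_summary[c]["sd"] for c in conds]
    fig, ax = plt.subplots(figsize=(4, 3.2))
    ax.bar(conds, means, yerr=sds, capsize=4, color=["tab:blue", "tab:green"])
    ax.set_ylabel("ln band power (ln mm$^2$)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_baselines(baseline_summary: dict, path=None):
    """Bar chart of mean 50-s baseline per condition (error bars: SE)."""
    plt = _plt()
    conds = list(baseline_summary)
    means = [baseline_summary[c]["mean_mm"] for c in conds]
    ses = [baseline_summary[c]["se_mm"] for c in conds]
    fig, ax = plt.subplots(figsize=(4, 3.2))
    ax.bar(conds, means, yerr=ses, capsize=4,
           color=["tab:orange", "tab:blue", "tab:green"][:len(conds)])
    ax.set_ylabel("baseline diameter (mm)")
    lo = min(means) - 4 * max(ses + [0.01])
    hi = max(means) + 4 * max(ses + [0.01])
    ax.set_ylim(lo, hi)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
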