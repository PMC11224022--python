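"""Figure-style plotting helpers for the standard analyses.

Each function draws onto a provided axes (or a fresh one) and returns it,
so panels compose into larger figures.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "plot_performance",
    "plot_acg_pi",
    "plot_phase_histogram",
    "plot_pair_matrix",
    "plot_sd_vs_mean",
]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_performance(trials, ax=None):
    """Produced vs actual vector with the regression line."""
    from .task import performance_slope

    ax = _ax(ax)
    ax.plot(trials["v_a"], trials["v_p"], "ko", ms=3, alpha=0.5)
    res = performance_slope(trials)
    x = np.array([trials["v_a"].min(), trials["v_a"].max()])
    ax.plot(x, res["slope"] * x + res["intercept"], "r-",
            label=f"slope = {res['slope']:.2f}")
    ax.axline((0, 0), slope=1, color="grey", lw=0.5)
    ax.set_xlabel("actual vector $v_a$ (s)")
    ax.set_ylabel("produced vector $v_p$ (s)")
    ax.legend(frameon=False)
    return ax


def plot_acg_pi(result, ax=None):
    """Mean ACG and PI curve of one unit (two stacked panels)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(2, 1, sharex=False)
    ax[0].plot(result.acg_lags, result.acg, "r-")
    ax[0].set_xlabel("lag (s)")
    ax[0].set_ylabel("ACG")
    ax[1].plot(result.pi_lags, result.pi_curve, "k-")
    if np.isfinite(result.null_mean):
        ax[1].axhline(result.null_mean + 2 * result.null_sd, color="grey",
                      ls="--", label="null mean + 2 SD")
        ax[1].legend(frameon=False)
    if np.isfinite(result.peak_lag):
        ax[1].axvline(result.peak_lag, color="r", lw=0.5)
    ax[1].set_xlabel("lag (s)")
    ax[1].set_ylabel("PI")
    return ax


def plot_phase_histogram(results, ax=None, bins=None):
    """Distribution of 1st/2nd/3rd pre-offset peak phases across units."""
    ax = _ax(ax)
    if bins is None:
        bins = np.arange(-2.5, 0.01, 0.05)
    colors = ("tab:blue", "tab:red", "tab:green")
    for j, c in enumerate(colors):
        vals = [r.phases[j] for r in results if np.isfinite(r.phases[j])]
        ax.hist(vals, bins=bins, color=c, alpha=0.6, label=f"peak {j + 1}")
    for k in (1, 2, 3):
        ax.axvline(-0.65 * k, color="grey", lw=0.5, ls=":")
    ax.set_xlabel("phase relative to joystick offset (s)")
    ax.set_ylabel("units")
    ax.legend(frameon=False)
    return ax


def plot_pair_matrix(pairs, order=None, ax=None):
    """Heat-map of pairwise zero-lag correlations (rank order reusable)."""
    ax = _ax(ax)
    vals = np.array([p.zero_lag for p in pairs])
    if order is None:
        order = np.argsort(vals)[::-1]
    ax.imshow(vals[order][None, :], aspect="auto", cmap="RdBu_r",
              vmin=-1, vmax=1)
    ax.set_yticks([])
    ax.set_xlabel("pair (rank ordered)")
    return ax


def plot_sd_vs_mean(results_by_label, ax=None):
    """sd vs mean of produced durations with fitted power laws."""
    ax = _ax(ax)
    for label, res in results_by_label.items():
        d = res.model.durations
        m = np.nanmean(d, axis=1)
        s = np.nanstd(d, axis=1, ddof=1)
        (line,) = ax.plot(m, s, "o", label=f"{label} (b = {res.b:.2f})")
        grid = np.linspace(m.min(), m.max(), 100)
        ax.plot(grid, res.a * grid**res.b + res.c, "-", color=line.get_color())
    ax.set_xlabel("mean produced duration (s)")
    ax.set_ylabel("s.d. (s)")
    ax.legend(frameon=False)
    return ax
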