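"""Publication-style plots: metric scatter with fit, Bland–Altman, and
group strip/box panels.  All functions return the matplotlib Figure."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stats import AgreementResult, pearson_regression

__all__ = ["scatter_with_fit", "bland_altman_plot", "group_comparison_plot"]


def scatter_with_fit(x, y, xlabel: str, ylabel: str, out_path=None):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    slope, intercept, r2, _ = pearson_regression(x, y)
    fig, ax = plt.subplots(figsize=(4.2, 4.0))
    ax.plot(x, y, "o", ms=4, color="0.2", alpha=0.7)
    xs = np.array([x.min(), x.max()])
    sign = "-" if intercept < 0 else "+"
    ax.plot(xs, slope * xs + intercept, "k-",
            label=f"y = {slope:.2f}x {sign} {abs(intercept):.2f}, r$^2$ = {r2:.2f}")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def bland_altman_plot(x, y, result: AgreementResult, labels=("A", "B"), out_path=None):
    x = np.asarray(x, float)
    mean_axis = (x + (x + result.differences)) / 2.0
    fig, ax = plt.subplots(figsize=(4.2, 3.4))
    ax.plot(mean_axis, result.differences, "o", ms=4, color="0.2", alpha=0.7)
    for v, style in ((result.mean_diff, "-"), (result.loa_low, "--"), (result.loa_high, "--")):
        ax.axhline(v, color="k", ls=style, lw=0.8)
    ax.set_xlabel(f"mean of {labels[0]} and corrected {labels[1]}")
    ax.set_ylabel(f"corrected {labels[1]} − {labels[0]}")
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def group_comparison_plot(values_by_group: dict[str, np.ndarray], metric: str,
                          threshold: float | None = None, out_path=None):
    """Box + strip panel per group; optional dashed optimal threshold.
    Boxes use the standard 1.5*IQR whisker rule (display only)."""
    fig, ax = plt.subplots(figsize=(3.2, 4.0))
    names = list(values_by_group)
    data = [np.asarray(values_by_group[g], float) for g in names]
    ax.boxplot(data, tick_labels=names, whis=1.5, sym="x")
    rng = np.random.default_rng(0)
    for i, vals in enumerate(data, start=1):
        ax.plot(i + rng.uniform(-0.08, 0.08, vals.size), vals, "o", ms=3, alpha=0.6)
    if threshold is not None:
        ax.axhline(threshold, color="k", ls="--", lw=0.8)
    ax.set_ylabel(metric)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
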