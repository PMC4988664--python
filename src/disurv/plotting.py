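"""Step plots for survival curves, smoothed hazard curves and the
actual-vs-predicted comparison of the discrete-time network model.

All plots are a thin presentation layer over the module results; tables
remain the authoritative output.  ``bw=True`` switches every curve to black
with distinct line styles so the figures survive grayscale printing.
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import ConfigurationError

__all__ = ["plot_km", "plot_hazard", "plot_ann_comparison", "save_figure"]

_BW_STYLES = ["-", "--", "-.", ":", (0, (3, 1, 1, 1))]
FORMATS = ("png", "pdf", "eps")


def _style(i, bw):
    if bw:
        return {"color": "black", "linestyle": _BW_STYLES[i % len(_BW_STYLES)]}
    return {}


def plot_km(curves, ci=False, risk_table_grid=None, bw=False):
    """Kaplan-Meier step plot, optionally with band and number-at-risk table."""
    from .km import risk_table as _risk_table
    nrows = 2 if risk_table_grid is not None else 1
    fig, axes = plt.subplots(
        nrows, 1, figsize=(7, 5.5 if nrows == 2 else 4.5),
        gridspec_kw={"height_ratios": [4, 1]} if nrows == 2 else None)
    ax = axes[0] if nrows == 2 else axes
    for i, (name, curve) in enumerate(curves.items()):
        t = np.concatenate([[0.0], curve.event_times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=str(name) if name is not None else None,
                **_style(i, bw))
        if ci:
            lo = np.concatenate([[1.0], curve.ci_low])
            hi = np.concatenate([[1.0], curve.ci_high])
            ax.fill_between(t, lo, hi, step="post", alpha=0.15,
                            color="black" if bw else None)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(-0.02, 1.02)
    if any(name is not None for name in curves):
        ax.legend()
    if risk_table_grid is not None:
        table = _risk_table(curves, risk_table_grid)
        tab_ax = axes[1]
        tab_ax.axis("off")
        tab_ax.table(cellText=table.values.astype(int),
                     rowLabels=[str(r) for r in table.index],
                     colLabels=[f"{c:g}" for c in table.columns],
                     loc="center")
        tab_ax.set_title("number at risk", fontsize=9)
    fig.tight_layout()
    return fig


def plot_hazard(curves, ci=False, bw=False, annotate_max=True):
    """Smoothed hazard curves with the maximum-hazard annotation."""
    if not isinstance(curves, dict):
        curves = {None: curves}
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for i, (name, curve) in enumerate(curves.items()):
        ax.plot(curve.grid, curve.values,
                label=str(name) if name is not None else None, **_style(i, bw))
        if ci and curve.ci_low is not None:
            ax.fill_between(curve.grid, curve.ci_low, curve.ci_high,
                            alpha=0.15, color="black" if bw else None)
        if annotate_max:
            ax.annotate(f"max {curve.max_value:.3g} @ t={curve.max_time:.3g}",
                        xy=(curve.max_time, curve.max_value),
                        xytext=(4, 4), textcoords="offset points", fontsize=8)
    ax.set_xlabel("time")
    ax.set_ylabel("hazard rate")
    if any(name is not None for name in curves):
        ax.legend()
    fig.tight_layout()
    return fig


def plot_ann_comparison(boundaries, actual_survival, predicted_survival, bw=False):
    """Actual discrete-time survival curve of a subject vs the model's."""
    b = np.asarray(boundaries, dtype=float)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.step(b[:-1], actual_survival, where="post", label="actual",
            **({"color": "black", "linestyle": ":"} if bw else {"linestyle": ":"}))
    ax.step(b[:-1], predicted_survival, where="post", label="predicted",
            **({"color": "black"} if bw else {}))
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    return fig


def save_figure(fig, path, fmt=None):
    path = str(path)
    fmt = fmt or path.rsplit(".", 1)[-1].lower()
    if fmt not in FORMATS:
        raise ConfigurationError(f"format must be one of {FORMATS}")
    fig.savefig(path, format=fmt)
    plt.close(fig)
    return path
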