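"""Kernel-smoothed hazard-rate estimation from right-censored data.

The estimator convolves the Nelson-Aalen increments dH(t_i) = m_i/n_i with
an Epanechnikov kernel of fixed bandwidth b:

    h(t) = (1/b) sum_i K((t - t_i)/b) dH(t_i)

Within one bandwidth of the origin or of the largest observed time t_D the
symmetric kernel leaks mass outside the data support; there it is replaced
by an asymmetric boundary kernel of the Gasser-Mueller type — the member of
the linear-times-Epanechnikov family (a + b x) K(x) on [-1, q] whose zeroth
moment is 1 and first moment 0, so the estimator keeps its second-order
behaviour up to the edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import ValidationError
from .io_model import SurvivalDataset

__all__ = [
    "HazardCurve",
    "nelson_aalen",
    "epanechnikov",
    "boundary_kernel",
    "smooth_hazard",
]


@dataclass(frozen=True)
class HazardCurve:
    grid: np.ndarray
    values: np.ndarray            # events per unit time
    bandwidth: float
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    @property
    def max_value(self) -> float:
        return float(np.max(self.values))

    @property
    def max_time(self) -> float:
        return float(self.grid[int(np.argmax(self.values))])


def nelson_aalen(ds: SurvivalDataset):
    """Nelson-Aalen increments m_i/n_i at the distinct event times.

    Returns ``(event_times, increments, at_risk, events)``; the cumulative
    hazard estimate is the running sum of the increments.
    """
    time, status = ds.time, ds.status
    if status.sum() == 0:
        raise ValidationError("no events: the Nelson-Aalen estimate is empty")
    order = np.argsort(time, kind="stable")
    time, status = time[order], status[order]
    event_times = np.unique(time[status == 1])
    at_risk = len(time) - np.searchsorted(time, event_times, side="left")
    te = np.sort(time[status == 1])
    events = (np.searchsorted(te, event_times, side="right")
              - np.searchsorted(te, event_times, side="left"))
    return event_times, events / at_risk, at_risk, events


def epanechnikov(x):
    """K(x) = (3/4)(1 - x^2) on [-1, 1], zero outside."""
    x = np.asarray(x, dtype=float)
    return np.where(np.abs(x) <= 1.0, 0.75 * (1.0 - x ** 2), 0.0)


def _epa_moments(q: float):
    """Integrals of x^j (3/4)(1 - x^2) over [-1, q] for j = 0, 1, 2."""
    def f0(x):
        return 0.75 * (x - x ** 3 / 3.0)

    def f1(x):
        return 0.75 * (x ** 2 / 2.0 - x ** 4 / 4.0)

    def f2(x):
        return 0.75 * (x ** 3 / 3.0 - x ** 5 / 5.0)

    return (f0(q) - f0(-1.0), f1(q) - f1(-1.0), f2(q) - f2(-1.0))


def boundary_kernel(x, q: float):
    """Left-boundary kernel (a + b x) K(x) on [-1, q].

    The coefficients solve the moment conditions int K_q = 1 and
    int x K_q = 0 over [-1, q]; q = 1 recovers the interior Epanechnikov
    kernel.  The right boundary is handled by reflection, K_q(-x).
    """
    if not 0.0 <= q <= 1.0:
        raise ValidationError("relative boundary position q must lie in [0, 1]")
    i0, i1, i2 = _epa_moments(q)
    det = i0 * i2 - i1 * i1
    a = i2 / det
    b = -i1 / det
    x = np.asarray(x, dtype=float)
    inside = (x >= -1.0) & (x <= q)
    return np.where(inside, (a + b * x) * 0.75 * (1.0 - x ** 2), 0.0)


def smooth_hazard(
    ds: SurvivalDataset,
    bandwidth: float,
    grid=None,
    grid_points: int = 101,
    ci: bool = False,
    level: float = 0.95,
) -> HazardCurve:
    """Fixed-bandwidth kernel-smoothed hazard rate on a time grid.

    The default grid is ``grid_points`` equally spaced points on [0, t_D]
    with t_D the largest observed time.  Near the edges (t < b or
    t > t_D - b) the boundary kernels take over; when the bandwidth exceeds
    half the data range the side closer to the evaluation point wins.

    With ``ci=True`` a pointwise band is attached using the asymptotic
    variance (1/b^2) sum K^2 m_i / (n_i (n_i - m_i)) and normal quantiles.
    """
    if bandwidth <= 0:
        raise ValidationError("bandwidth must be positive")
    event_times, dH, at_risk, events = nelson_aalen(ds)
    t_max = float(np.max(ds.time))
    if grid is None:
        grid = np.linspace(0.0, t_max, grid_points)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0) or np.any(grid > t_max):
        raise ValidationError("grid must lie within [0, t_D]")

    b = float(bandwidth)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_terms = np.where(at_risk > events,
                             events / (at_risk * (at_risk - events).astype(float)),
                             0.0)
    values = np.empty_like(grid)
    variance = np.empty_like(grid)
    for j, t in enumerate(grid):
        x = (t - event_times) / b
        q_left = t / b
        q_right = (t_max - t) / b
        if q_left >= 1.0 and q_right >= 1.0:
            k = epanechnikov(x)
        elif q_left <= q_right:
            k = boundary_kernel(x, min(q_left, 1.0))
        else:
            k = boundary_kernel(-x, min(q_right, 1.0))
        values[j] = np.sum(k * dH) / b
        variance[j] = np.sum(k ** 2 * var_terms) / b ** 2
    # the linear part of a boundary kernel can dip negative; a hazard cannot
    values = np.clip(values, 0.0, None)

    if np.all(values == 0.0):
        warnings.warn("bandwidth so small that no event falls within reach of "
                      "any grid point; the smoothed curve is identically zero")
    lo = hi = None
    if ci:
        z = norm.ppf(0.5 + level / 2.0)
        sd = np.sqrt(variance)
        lo = np.clip(values - z * sd, 0.0, None)
        hi = values + z * sd
    return HazardCurve(grid=grid, values=values, bandwidth=b,
                       ci_low=lo, ci_high=hi)


def event_histogram(ds: SurvivalDataset, bin_width: float):
    """Event counts on equal-width bins over [0, t_D] (plot overlay)."""
    if bin_width <= 0:
        raise ValidationError("bin width must be positive")
    t_max = float(np.max(ds.time))
    edges = np.arange(0.0, t_max + bin_width, bin_width)
    if edges[-1] < t_max:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(ds.time[ds.status == 1], bins=edges)
    return counts, edges
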