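"""Kaplan-Meier survival estimation.

Implements the product-limit estimator S(t) = prod_{t_i <= t} (1 - m_i/n_i)
over the distinct observed event times, with the Greenwood variance, a
95% confidence band (log-transformed by default, matching the convention of
the R ``survival`` package), the median survival time, the median follow-up
time by reverse Kaplan-Meier, and the number-at-risk table.

Subjects censored at an event time are counted in the risk set at that time
(events precede censorings at ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError
from .io_model import SurvivalDataset

__all__ = [
    "KMCurve",
    "fit_km",
    "median_survival",
    "median_followup",
    "risk_table",
    "km_confidence_band",
]


@dataclass(frozen=True)
class KMCurve:
    """A fitted Kaplan-Meier step function.

    All per-time arrays are aligned on ``event_times``, the ordered distinct
    times with at least one event.  ``survival`` holds the step value just
    after each event time; S(t) = 1 before the first event time.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_total: int
    n_events: int
    label: str | None = None
    _times_all: np.ndarray | None = None  # observed times incl. censorings

    @property
    def median(self) -> float | None:
        return median_survival(self)

    def survival_at(self, times) -> np.ndarray:
        """Step-function evaluation of S(t) at arbitrary times."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.searchsorted(self.event_times, times, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times,
            "n_risk": self.at_risk,
            "n_event": self.events,
            "survival": self.survival,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        })


def _fit_single(time: np.ndarray, status: np.ndarray, label=None) -> KMCurve:
    order = np.argsort(time, kind="stable")
    time, status = time[order], status[order]
    n = len(time)
    event_times = np.unique(time[status == 1])
    # risk set just before t_i: everyone with observed time >= t_i
    at_risk = n - np.searchsorted(time, event_times, side="left")
    events = np.array([int(np.sum((time == t) & (status == 1)))
                       for t in event_times])
    frac = np.divide(events, at_risk, dtype=float)
    survival = np.cumprod(1.0 - frac)
    # Greenwood: var(S) = S^2 * sum m / (n (n - m))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = events / (at_risk * (at_risk - events).astype(float))
        gw = np.cumsum(gw_terms)
        se = survival * np.sqrt(gw)  # NaN once S reaches 0 (variance undefined)
    lo, hi = _log_band(survival, gw, 0.95)
    return KMCurve(
        event_times=event_times,
        at_risk=at_risk,
        events=events,
        survival=survival,
        se=se,
        ci_low=lo,
        ci_high=hi,
        n_total=n,
        n_events=int(np.sum(status == 1)),
        label=label,
        _times_all=time,
    )


def fit_km(ds: SurvivalDataset, group: str | None = None) -> dict:
    """Fit the product-limit estimator, optionally one curve per group level.

    Returns a mapping from group level to :class:`KMCurve`; with no group
    the single curve is stored under the key ``None``.
    """
    if group is None and ds.group_col is not None:
        group = ds.group_col
    if group is None:
        return {None: _fit_single(ds.time, ds.status)}
    if group not in ds.frame.columns:
        raise ValidationError(f"group column {group!r} not present")
    col = ds.frame[group]
    levels = (list(col.cat.categories) if isinstance(col.dtype, pd.CategoricalDtype)
              else sorted(col.dropna().unique()))
    curves = {}
    for level in levels:
        mask = (col == level).to_numpy()
        if not mask.any():
            raise ValidationError(f"group level {level!r} has no subjects")
        curves[level] = _fit_single(ds.time[mask], ds.status[mask], label=str(level))
    return curves


def median_survival(curve: KMCurve) -> float | None:
    """Smallest event time at which S(t) drops to 0.5 or below; None if never."""
    hit = np.nonzero(curve.survival <= 0.5)[0]
    return float(curve.event_times[hit[0]]) if len(hit) else None


def median_followup(ds: SurvivalDataset) -> float | None:
    """Median follow-up by reverse Kaplan-Meier (censoring indicator flipped)."""
    flipped = ds.flip_status()
    return median_survival(fit_km(flipped)[None])


def risk_table(curves, grid) -> pd.DataFrame:
    """Number of subjects still under observation at each grid time, per curve."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) < 0):
        raise ValidationError("grid must be non-empty and non-decreasing")
    if isinstance(curves, KMCurve):
        curves = {curves.label: curves}
    rows = {}
    for name, curve in curves.items():
        times = curve._times_all
        rows[name if name is not None else "all"] = [
            int(np.sum(times >= g)) for g in grid
        ]
    return pd.DataFrame(rows, index=pd.Index(grid, name="time")).T


def _log_band(survival, gw_cumsum, level):
    """Greenwood band on the log-survival scale: S * exp(+-z * se(log S))."""
    z = norm.ppf(0.5 + level / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_log = np.sqrt(gw_cumsum)
        lo = survival * np.exp(-z * se_log)
        hi = survival * np.exp(z * se_log)
    lo = np.where(survival > 0, np.clip(lo, 0.0, 1.0), np.nan)
    hi = np.where(survival > 0, np.clip(hi, 0.0, 1.0), np.nan)
    # a flat S = 1 segment has zero Greenwood variance: degenerate band at 1
    lo = np.where(survival == 1.0, 1.0, lo)
    hi = np.where(survival == 1.0, 1.0, hi)
    return lo, hi


def km_confidence_band(curve: KMCurve, level: float = 0.95,
                       transform: str = "log") -> tuple[np.ndarray, np.ndarray]:
    """Recompute the confidence band at an arbitrary coverage level.

    ``transform="log"`` (default) applies the normal quantile on the log-S
    scale; ``transform="plain"`` is the untransformed Greenwood band
    S +- z * se(S), clipped to [0, 1].
    """
    if not 0 < level < 1:
        raise ValidationError("level must lie in (0, 1)")
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.where(curve.survival > 0,
                      (curve.se / np.where(curve.survival > 0, curve.survival, 1.0)) ** 2,
                      np.inf)
    if transform == "log":
        return _log_band(curve.survival, gw, level)
    if transform == "plain":
        z = norm.ppf(0.5 + level / 2.0)
        lo = np.clip(curve.survival - z * curve.se, 0.0, 1.0)
        hi = np.clip(curve.survival + z * curve.se, 0.0, 1.0)
        return lo, hi
    raise ValidationError(f"unknown transform {transform!r}")
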