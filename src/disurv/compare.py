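"""Weighted log-rank tests for comparing k >= 2 survival curves.

At every distinct pooled event time t_i the observed events per group are
compared with the expected events e_gi = n_gi * m_i / n_i under the null of
a common hazard.  The weighted sums of (O - E) over times are referred to a
chi-square distribution with k - 1 degrees of freedom through the
hypergeometric covariance of the per-time 2xk tables.

Weight schemes
--------------
log-rank      w_i = 1
peto-peto     w_i = pooled left-continuous Kaplan-Meier estimate S(t_i-)
tarone-ware   w_i = sqrt(n_i)

For two groups the odds ratio (O_X/e_X) / (O_Y/e_Y) — the ratio of the
groups' relative death rates — is reported alongside the test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import ConfigurationError, ValidationError
from .io_model import SurvivalDataset

__all__ = ["WeightedTestResult", "compare_curves", "odds_ratio", "SCHEMES"]

SCHEMES = ("log-rank", "peto-peto", "tarone-ware")


@dataclass(frozen=True)
class WeightedTestResult:
    per_group: pd.DataFrame     # level, n, events (O), expected (e)
    statistic: float
    df: int
    p_value: float
    weights_used: str

    @property
    def odds_ratio(self) -> float | None:
        if len(self.per_group) != 2:
            return None
        return odds_ratio(self)


def _per_time_tables(time, status, labels, levels):
    """Risk-set size and event count per group at every pooled event time."""
    event_times = np.unique(time[status == 1])
    k = len(levels)
    n_gi = np.empty((len(event_times), k), dtype=float)
    m_gi = np.empty((len(event_times), k), dtype=float)
    for g, level in enumerate(levels):
        mask = labels == level
        tg = np.sort(time[mask])
        n_gi[:, g] = len(tg) - np.searchsorted(tg, event_times, side="left")
        te = np.sort(time[mask & (status == 1)])
        m_gi[:, g] = (np.searchsorted(te, event_times, side="right")
                      - np.searchsorted(te, event_times, side="left"))
    return event_times, n_gi, m_gi


def compare_curves(ds: SurvivalDataset, group: str | None = None,
                   scheme: str = "log-rank") -> WeightedTestResult:
    """Run one of the weighted tests over the levels of a group column."""
    if scheme not in SCHEMES:
        raise ConfigurationError(f"scheme must be one of {SCHEMES}")
    if group is None:
        group = ds.group_col
    if group is None or group not in ds.frame.columns:
        raise ConfigurationError(f"group column {group!r} not present")
    col = ds.frame[group]
    levels = (list(col.cat.categories) if isinstance(col.dtype, pd.CategoricalDtype)
              else sorted(col.dropna().unique()))
    k = len(levels)
    if k < 2:
        raise ValidationError("need at least two group levels to compare")
    time, status = ds.time, ds.status
    labels = col.to_numpy()
    if status.sum() == 0:
        raise ValidationError("no events observed; the statistic is undefined")

    event_times, n_gi, m_gi = _per_time_tables(time, status, labels, levels)
    n_i = n_gi.sum(axis=1)
    m_i = m_gi.sum(axis=1)

    if scheme == "log-rank":
        w = np.ones_like(n_i)
    elif scheme == "tarone-ware":
        w = np.sqrt(n_i)
    else:  # peto-peto: pooled KM just before t_i
        s = np.cumprod(1.0 - m_i / n_i)
        w = np.concatenate([[1.0], s[:-1]])

    e_gi = n_gi * (m_i / n_i)[:, None]
    observed = m_gi.sum(axis=0)
    expected = e_gi.sum(axis=0)

    # hypergeometric covariance of the per-time event counts
    with np.errstate(divide="ignore", invalid="ignore"):
        c_i = np.where(n_i > 1, m_i * (n_i - m_i) / (n_i ** 2 * (n_i - 1.0)), 0.0)
    u = (w[:, None] * (m_gi - e_gi)).sum(axis=0)          # length k
    # V_gh = sum_i w_i^2 c_i (delta_gh n_gi n_i - n_gi n_hi)
    wc = (w ** 2) * c_i
    V = -np.einsum("i,ig,ih->gh", wc, n_gi, n_gi)
    V[np.diag_indices(k)] += np.einsum("i,ig->g", wc * n_i, n_gi)

    u_r, V_r = u[:-1], V[:-1, :-1]
    try:
        stat = float(u_r @ np.linalg.solve(V_r, u_r))
    except np.linalg.LinAlgError:
        stat = float(u_r @ np.linalg.pinv(V_r) @ u_r)
    stat = max(stat, 0.0)
    df = k - 1
    p = float(chi2.sf(stat, df))

    per_group = pd.DataFrame({
        "level": levels,
        "n": [int(np.sum(labels == lv)) for lv in levels],
        "events": observed.astype(int),
        "expected": expected,
    })
    return WeightedTestResult(per_group=per_group, statistic=stat, df=df,
                              p_value=p, weights_used=scheme)


def odds_ratio(result: WeightedTestResult) -> float | None:
    """(O_X/e_X) / (O_Y/e_Y) for a two-group comparison.

    Returns None (undefined) when a group has zero expected events.
    """
    if len(result.per_group) != 2:
        raise ValidationError("odds ratio is defined for exactly two groups")
    o = result.per_group["events"].to_numpy(dtype=float)
    e = result.per_group["expected"].to_numpy(dtype=float)
    if e[0] == 0 or e[1] == 0 or o[1] == 0:
        return None
    return float((o[0] / e[0]) / (o[1] / e[1]))
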