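"""Data model for right-censored survival data.

A :class:`SurvivalDataset` wraps a pandas DataFrame with declared roles for
the follow-up time column, the censorship status column (0 = censored,
1 = event), covariate columns and an optional group label.  The module also
houses CSV ingestion with column mapping, covariate stratification /
regrouping, and a synthetic-cohort generator that draws subjects from known
per-interval discrete hazards so that every estimator in the package can be
tested against a ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalDataset",
    "SyntheticTruth",
    "DiscreteHazardModel",
    "load_csv",
    "stratify",
    "regroup",
    "generate_cohort",
    "jitter_event_times",
]


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored survival data with declared column roles.

    Parameters
    ----------
    frame
        One row per subject.  Must contain ``time_col`` and ``status_col``.
    time_col, status_col
        Names of the follow-up-time and censorship-status columns.  Status is
        coded 0 = censored, 1 = event.
    covariate_cols
        Names of predictor columns (numeric or categorical).
    group_col
        Optional categorical label used to split the cohort into curves.
    """

    frame: pd.DataFrame
    time_col: str
    status_col: str
    covariate_cols: tuple[str, ...] = ()
    group_col: str | None = None

    def __post_init__(self) -> None:
        for col in (self.time_col, self.status_col, *self.covariate_cols):
            if col not in self.frame.columns:
                raise ConfigurationError(f"column {col!r} not present in data")
        if self.group_col is not None and self.group_col not in self.frame.columns:
            raise ConfigurationError(f"group column {self.group_col!r} not present")
        names = list(self.covariate_cols)
        if len(set(names)) != len(names) or any(not n for n in names):
            raise ConfigurationError("covariate names must be unique and non-empty")
        if len(self.frame) < 1:
            raise ValidationError("dataset must contain at least one subject")
        t = pd.to_numeric(self.frame[self.time_col], errors="coerce")
        bad = self.frame.index[t.isna() | (t < 0)]
        if len(bad):
            raise ValidationError(
                f"non-numeric or negative follow-up time at rows {list(bad[:10])}"
            )
        s = self.frame[self.status_col]
        bad = self.frame.index[~s.isin([0, 1])]
        if len(bad):
            raise ValidationError(
                f"status outside {{0, 1}} at rows {list(bad[:10])}"
            )

    # -- array views ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def time(self) -> np.ndarray:
        return self.frame[self.time_col].to_numpy(dtype=float)

    @property
    def status(self) -> np.ndarray:
        return self.frame[self.status_col].to_numpy(dtype=int)

    @property
    def covariates(self) -> pd.DataFrame:
        return self.frame[list(self.covariate_cols)]

    @property
    def group(self) -> pd.Series | None:
        return None if self.group_col is None else self.frame[self.group_col]

    def with_frame(self, frame: pd.DataFrame) -> "SurvivalDataset":
        return replace(self, frame=frame)

    def with_group(self, column: str) -> "SurvivalDataset":
        return replace(self, group_col=column)

    def flip_status(self) -> "SurvivalDataset":
        """Swap the censorship indicator (events become censorings).

        This is how the censoring-time distribution (reverse Kaplan-Meier)
        is estimated.
        """
        frame = self.frame.copy()
        frame[self.status_col] = 1 - self.status
        return self.with_frame(frame)

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def load_csv(
    path,
    time_column: str,
    status_column: str,
    covariate_columns: Sequence[str] = (),
    group_column: str | None = None,
    event_code=1,
    censor_code=0,
) -> SurvivalDataset:
    """Read a CSV of survival data and declare the column roles.

    Rows whose time or status cannot be parsed are dropped and their row
    indices reported through the module logger.  A negative time or a status
    outside ``{event_code, censor_code}`` raises :class:`ValidationError`
    naming the offending rows.  Rows with missing covariate values are
    dropped with a logged count.
    """
    frame = pd.read_csv(path)
    for col in (time_column, status_column, *covariate_columns):
        if col not in frame.columns:
            raise ConfigurationError(f"declared column {col!r} missing from {path}")

    t = pd.to_numeric(frame[time_column], errors="coerce")
    s = pd.to_numeric(frame[status_column], errors="coerce")
    unparseable = frame.index[(t.isna() & frame[time_column].notna())
                              | (s.isna() & frame[status_column].notna())
                              | frame[time_column].isna()
                              | frame[status_column].isna()]
    if len(unparseable):
        logger.warning(
            "dropping %d rows with unparseable time/status: rows %s",
            len(unparseable), list(unparseable[:20]),
        )
        frame = frame.drop(index=unparseable)
        t = t.drop(index=unparseable)
        s = s.drop(index=unparseable)

    neg = frame.index[t < 0]
    if len(neg):
        raise ValidationError(f"negative follow-up time at rows {list(neg[:10])}")
    valid_codes = {event_code, censor_code}
    bad = frame.index[~s.isin(valid_codes)]
    if len(bad):
        raise ValidationError(
            f"status not in {sorted(valid_codes)} at rows {list(bad[:10])}"
        )

    frame = frame.copy()
    frame[time_column] = t
    frame[status_column] = (s == event_code).astype(int)

    if covariate_columns:
        missing = frame[list(covariate_columns)].isna().any(axis=1)
        if missing.any():
            logger.warning("dropping %d rows with missing covariate values",
                           int(missing.sum()))
            frame = frame[~missing]

    frame = frame.reset_index(drop=True)
    return SurvivalDataset(
        frame=frame,
        time_col=time_column,
        status_col=status_column,
        covariate_cols=tuple(covariate_columns),
        group_col=group_column,
    )


def stratify(
    ds: SurvivalDataset,
    column: str,
    breakpoints: Sequence[float],
    labels: Sequence[str] | None = None,
    closed: str = "right",
) -> SurvivalDataset:
    """Replace a numeric column by categorical strata.

    The first interval is closed at both ends; with ``closed="right"``
    (default) every subsequent interval is left-open right-closed, so
    printed ranges like "39 to 45, 45 to 55" place a value equal to a shared
    breakpoint in the earlier stratum.  ``closed="left"`` flips the
    convention for the interior breakpoints.
    """
    if column not in ds.frame.columns:
        raise ConfigurationError(f"column {column!r} not present")
    bp = np.asarray(breakpoints, dtype=float)
    if bp.ndim != 1 or len(bp) < 2 or np.any(np.diff(bp) <= 0):
        raise ConfigurationError("breakpoints must be strictly increasing, >= 2")
    k = len(bp) - 1
    if labels is None:
        labels = [f"{_fmt(lo)}-{_fmt(hi)}" for lo, hi in zip(bp[:-1], bp[1:])]
    if len(labels) != k:
        raise ConfigurationError(f"need {k} labels, got {len(labels)}")

    values = pd.to_numeric(ds.frame[column], errors="coerce").to_numpy(dtype=float)
    out = ds.frame.index[(values < bp[0]) | (values > bp[-1]) | np.isnan(values)]
    if len(out):
        raise ValidationError(
            f"values of {column!r} outside [{bp[0]}, {bp[-1]}] at rows {list(out[:10])}"
        )
    if closed == "right":
        idx = np.searchsorted(bp, values, side="left") - 1
        idx[values == bp[0]] = 0
    elif closed == "left":
        idx = np.searchsorted(bp, values, side="right") - 1
        idx[values == bp[-1]] = k - 1
    else:
        raise ConfigurationError("closed must be 'right' or 'left'")

    frame = ds.frame.copy()
    frame[column] = pd.Categorical([labels[i] for i in idx], categories=list(labels))
    return ds.with_frame(frame)


def _fmt(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else f"{x:g}"


def regroup(
    ds: SurvivalDataset,
    column: str,
    merge_map: Mapping,
) -> SurvivalDataset:
    """Merge and rename categories of a categorical column.

    Every key of ``merge_map`` must be an existing category; categories not
    mentioned are left unchanged.
    """
    if column not in ds.frame.columns:
        raise ConfigurationError(f"column {column!r} not present")
    col = ds.frame[column]
    present = set(col.dropna().unique())
    absent = [k for k in merge_map if k not in present]
    if absent:
        raise ValidationError(f"categories {absent} not present in {column!r}")
    if not merge_map:
        return ds
    frame = ds.frame.copy()
    mapped = col.map(lambda v: merge_map.get(v, v))
    # preserve first-appearance order of the resulting labels
    categories = list(dict.fromkeys(mapped.dropna()))
    frame[column] = pd.Categorical(mapped, categories=categories)
    return ds.with_frame(frame)


# ---------------------------------------------------------------------------
# Synthetic cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscreteHazardModel:
    """Discrete-time hazard model on G intervals with log-odds covariate effects.

    The hazard of a subject with covariate vector x in interval t is
    ``expit(logit(baseline[t]) + sum_j effects[j] * x_j)`` — a logistic model
    on the per-interval conditional event probability.

    ``covariate_dists`` describes how covariates are drawn per subject:
    ``("bernoulli", p)``, ``("normal", mu, sd)`` or ``("choice", [values])``.
    Effects may only reference numerically-valued covariates.
    """

    baseline: Sequence[float]
    effects: Mapping[str, float] = field(default_factory=dict)
    covariate_dists: Mapping[str, tuple] = field(default_factory=dict)

    def baseline_array(self, intervals: int) -> np.ndarray:
        base = np.asarray(self.baseline, dtype=float)
        if base.ndim == 0:
            base = np.full(intervals, float(base))
        if base.shape != (intervals,):
            raise ConfigurationError(
                f"baseline hazards must have length {intervals}, got {base.shape}"
            )
        if np.any((base <= 0) | (base >= 1)):
            raise ConfigurationError("baseline hazards must lie in (0, 1)")
        return base


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth carried alongside a generated cohort.

    ``interval_hazards`` maps each covariate pattern (tuple of the values of
    the covariates that carry effects) to its true per-interval hazard;
    ``true_survival`` maps the same patterns to survival at the G+1 interval
    boundaries (starts at 1, running product of 1 - hazard).
    """

    interval_hazards: dict[tuple, np.ndarray]
    true_survival: dict[tuple, np.ndarray]
    censoring_rate: float
    seed: int


def generate_cohort(
    n: int,
    intervals: int,
    hazard_model: DiscreteHazardModel,
    censor_prob: float = 0.0,
    seed: int = 0,
) -> tuple[SurvivalDataset, SyntheticTruth]:
    """Draw a cohort by a discrete-time geometric walk over intervals 1..G.

    At each interval a still-at-risk subject experiences the event with its
    pattern hazard; otherwise it is censored with probability ``censor_prob``;
    otherwise it advances.  Subjects surviving past interval G are censored
    at G.  Follow-up times are recorded on the interval-index scale (1..G).
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if intervals < 2:
        raise ConfigurationError("interval count must be >= 2")
    if not 0 <= censor_prob < 1:
        raise ConfigurationError("censor_prob must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    base = hazard_model.baseline_array(intervals)

    cov_data: dict[str, np.ndarray] = {}
    for name, dist in hazard_model.covariate_dists.items():
        kind = dist[0]
        if kind == "bernoulli":
            cov_data[name] = (rng.random(n) < dist[1]).astype(float)
        elif kind == "normal":
            cov_data[name] = rng.normal(dist[1], dist[2], size=n)
        elif kind == "choice":
            cov_data[name] = rng.choice(np.asarray(dist[1]), size=n)
        else:
            raise ConfigurationError(f"unknown covariate distribution {kind!r}")
    for name in hazard_model.effects:
        if name not in cov_data:
            raise ConfigurationError(f"effect on undeclared covariate {name!r}")

    eta = np.zeros(n)
    for name, beta in hazard_model.effects.items():
        eta += beta * np.asarray(cov_data[name], dtype=float)
    hazards = expit(logit(base)[None, :] + eta[:, None])  # n x G

    time = np.full(n, intervals, dtype=float)
    status = np.zeros(n, dtype=int)
    active = np.ones(n, dtype=bool)
    for t in range(intervals):
        u_event = rng.random(n)
        u_cens = rng.random(n)
        event = active & (u_event < hazards[:, t])
        time[event] = t + 1
        status[event] = 1
        active &= ~event
        if censor_prob > 0:
            cens = active & (u_cens < censor_prob)
            time[cens] = t + 1
            active &= ~cens

    frame = pd.DataFrame({"time": time, "status": status, **cov_data})
    ds = SurvivalDataset(
        frame=frame,
        time_col="time",
        status_col="status",
        covariate_cols=tuple(cov_data),
    )

    effect_names = list(hazard_model.effects)
    if effect_names:
        pattern_of = frame[effect_names].apply(tuple, axis=1)
        patterns = sorted(set(pattern_of))
    else:
        patterns = [()]
    interval_hazards: dict[tuple, np.ndarray] = {}
    true_survival: dict[tuple, np.ndarray] = {}
    for pat in patterns:
        eta_p = sum(b * x for b, x in zip(
            (hazard_model.effects[nm] for nm in effect_names), pat))
        h = expit(logit(base) + eta_p)
        interval_hazards[pat] = h
        true_survival[pat] = np.concatenate([[1.0], np.cumprod(1.0 - h)])
    truth = SyntheticTruth(
        interval_hazards=interval_hazards,
        true_survival=true_survival,
        censoring_rate=float(np.mean(status == 0)),
        seed=seed,
    )
    return ds, truth


def jitter_event_times(ds: SurvivalDataset, width: float = 1.0,
                       seed: int = 0) -> SurvivalDataset:
    """Spread each event time uniformly over the interval it fell in.

    A cohort from :func:`generate_cohort` records events on the
    interval-index scale (atoms at 1, 2, ...).  Subtracting a U(0, width)
    offset from each event time gives the continuous-time view of the same
    cohort — an event in interval t happened somewhere in (t - width, t] —
    which is the natural input for the kernel hazard smoother.  Censoring
    times are left untouched.
    """
    rng = np.random.default_rng(seed)
    frame = ds.frame.copy()
    event = ds.status == 1
    times = frame[ds.time_col].to_numpy(dtype=float)
    times[event] = times[event] - rng.uniform(0.0, width, int(event.sum()))
    frame[ds.time_col] = times
    return ds.with_frame(frame)
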