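"""Contingency tables with marginals and the three association tests.

Tables are cross-tabulated from two categorical columns of a
:class:`~disurv.io_model.SurvivalDataset` (use ``stratify``/``regroup`` to
discretise numeric columns first).  Proportions can be displayed SPSS-style
(percentages) or SAS-style (unit scale); the style never changes counts or
test results.  Pearson chi-square, Fisher exact (2x2) and McNemar tests are
delegated to scipy/statsmodels; no continuity correction is applied unless
requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .errors import ConfigurationError, ValidationError
from .io_model import SurvivalDataset

__all__ = [
    "ContingencyTable",
    "build_table",
    "chi_square_test",
    "fisher_exact",
    "mcnemar",
]


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple
    col_labels: tuple
    counts: np.ndarray          # r x c non-negative integers
    style: str = "percent"      # "percent" (SPSS) or "unit" (SAS)

    def __post_init__(self):
        if self.style not in ("percent", "unit"):
            raise ConfigurationError("style must be 'percent' or 'unit'")
        if np.any(self.counts < 0):
            raise ValidationError("cell counts must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def row_proportions(self) -> np.ndarray:
        scale = 100.0 if self.style == "percent" else 1.0
        with np.errstate(invalid="ignore"):
            return scale * self.counts / self.row_totals[:, None]

    def col_proportions(self) -> np.ndarray:
        scale = 100.0 if self.style == "percent" else 1.0
        with np.errstate(invalid="ignore"):
            return scale * self.counts / self.col_totals[None, :]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.counts, index=list(self.row_labels),
                             columns=list(self.col_labels))
        frame["Total"] = self.row_totals
        frame.loc["Total"] = list(self.col_totals) + [self.grand_total]
        return frame


def _is_categorical(series: pd.Series) -> bool:
    if isinstance(series.dtype, pd.CategoricalDtype):
        return True
    if series.dtype == object or pd.api.types.is_bool_dtype(series):
        return True
    # small integer-valued columns count as categorical codes
    vals = series.dropna().unique()
    return len(vals) <= 10 and all(float(v).is_integer() for v in vals)


def _levels(series: pd.Series):
    if isinstance(series.dtype, pd.CategoricalDtype):
        return [lv for lv in series.cat.categories if (series == lv).any()]
    return sorted(series.dropna().unique())


def build_table(ds: SurvivalDataset, var_row: str, var_col: str,
                style: str = "percent") -> ContingencyTable:
    """Cross-tabulate two categorical variables with marginals."""
    for col in (var_row, var_col):
        if col not in ds.frame.columns:
            raise ConfigurationError(f"column {col!r} not present")
        if not _is_categorical(ds.frame[col]):
            raise ValidationError(
                f"column {col!r} is not categorical; apply stratify/regroup first"
            )
    rows = _levels(ds.frame[var_row])
    cols = _levels(ds.frame[var_col])
    counts = np.zeros((len(rows), len(cols)), dtype=int)
    for i, rv in enumerate(rows):
        for j, cv in enumerate(cols):
            counts[i, j] = int(np.sum((ds.frame[var_row] == rv)
                                      & (ds.frame[var_col] == cv)))
    return ContingencyTable(row_labels=tuple(rows), col_labels=tuple(cols),
                            counts=counts, style=style)


def chi_square_test(table: ContingencyTable, correction: bool = False):
    """Pearson chi-square test of independence: sum (O - E)^2 / E.

    Expected counts come from the marginal products; df = (r-1)(c-1).  No
    Yates continuity correction by default.
    """
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValidationError("need at least a 2x2 table")
    if table.grand_total < 1:
        raise ValidationError("empty table")
    expected = np.outer(table.row_totals, table.col_totals) / table.grand_total
    if np.any(expected == 0):
        raise ValidationError("a zero expected count makes the test undefined")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=correction)
    return float(stat), int(df), float(p)


def fisher_exact(table: ContingencyTable, alternative: str = "two-sided") -> float:
    """Fisher exact p for a 2x2 table.

    Two-sided p sums the hypergeometric probabilities of every table with
    the observed marginals whose probability does not exceed the observed
    one (the probability-ordering convention of R's fisher.test).
    """
    if table.counts.shape != (2, 2):
        raise ValidationError("Fisher exact test requires a 2x2 table")
    if np.any(table.row_totals < 1) or np.any(table.col_totals < 1):
        raise ValidationError("all marginals must be at least 1")
    res = stats.fisher_exact(table.counts, alternative=alternative)
    return float(res.pvalue)


def mcnemar(table: ContingencyTable, correction: bool = False):
    """McNemar test on the discordant cells of a paired 2x2 table.

    Statistic (b - c)^2 / (b + c) on 1 df, without continuity correction by
    default.  Requires identical row and column category labels (a paired
    design); returns ``(None, None)`` when both discordant cells are zero.
    """
    if table.counts.shape != (2, 2):
        raise ValidationError("McNemar test requires a 2x2 table")
    if tuple(table.row_labels) != tuple(table.col_labels):
        raise ValidationError(
            "McNemar requires identically labelled rows and columns"
        )
    b, c = int(table.counts[0, 1]), int(table.counts[1, 0])
    if b + c == 0:
        return None, None
    res = _sm_mcnemar(table.counts, exact=False, correction=correction)
    return float(res.statistic), float(res.pvalue)
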