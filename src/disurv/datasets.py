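"""Access to the classic clinical datasets shipped with R's survival package.

The bladder-cancer recurrence data (Wei, Lin & Weissfeld) and the advanced
lung-cancer data are exported on demand through ``Rscript`` and returned as
pandas DataFrames.  An installed R with the ``survival`` package is
required; :func:`r_available` reports whether that is the case.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError
from .io_model import SurvivalDataset, load_csv

__all__ = ["r_available", "load_r_dataset", "load_bladder_first_recurrence",
           "load_lung"]


def r_available() -> bool:
    return shutil.which("Rscript") is not None


def load_r_dataset(name: str) -> pd.DataFrame:
    """Export a dataset from the R survival package to a DataFrame."""
    if not r_available():
        raise ConfigurationError("Rscript not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        out = Path(tmp) / "data.csv"
        script = (
            f'suppressMessages(library(survival)); '
            f'write.csv({name}, "{out.as_posix()}", row.names=FALSE, na="")'
        )
        proc = subprocess.run(["Rscript", "-e", script],
                              capture_output=True, text=True)
        if proc.returncode != 0 or not out.exists():
            raise ConfigurationError(
                f"R export of {name!r} failed: {proc.stderr.strip()}"
            )
        return pd.read_csv(out)


def load_bladder_first_recurrence() -> SurvivalDataset:
    """Each bladder-cancer patient's first recurrence record (85 subjects).

    Covariates: rx (1 = placebo, 2 = thiotepa), number of tumours, size of
    the largest tumour; follow-up is `stop` with `event` the recurrence
    indicator.
    """
    frame = load_r_dataset("bladder")
    frame = frame[frame["enum"] == 1].reset_index(drop=True)
    with tempfile.TemporaryDirectory() as tmp:
        path = Path(tmp) / "bladder1st.csv"
        frame.to_csv(path, index=False)
        return load_csv(path, time_column="stop", status_column="event",
                        covariate_columns=("rx", "number", "size"))


def load_lung() -> SurvivalDataset:
    """The advanced lung-cancer cohort (status recoded to 0/1)."""
    frame = load_r_dataset("lung")
    frame["status"] = frame["status"] - 1   # 1/2 coding -> 0/1
    with tempfile.TemporaryDirectory() as tmp:
        path = Path(tmp) / "lung.csv"
        frame.to_csv(path, index=False)
        return load_csv(path, time_column="time", status_column="status",
                        covariate_columns=("age", "sex"))
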