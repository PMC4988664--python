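import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from disurv import SurvivalDataset

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_ds(times, status, group=None, **covariates) -> SurvivalDataset:
    """Build a small dataset from parallel lists."""
    data = {"time": np.asarray(times, dtype=float),
            "status": np.asarray(status, dtype=int)}
    if group is not None:
        data["group"] = group
    data.update(covariates)
    return SurvivalDataset(
        frame=pd.DataFrame(data),
        time_col="time",
        status_col="status",
        covariate_cols=tuple(covariates),
        group_col="group" if group is not None else None,
    )


@pytest.fixture
def toy3():
    """Three subjects: events at 1 and 3, a censoring at 2."""
    return make_ds([1, 2, 3], [1, 0, 1])


@pytest.fixture
def two_groups_disjoint():
    """Group X dies at {1, 2}, group Y at {3, 4}; no censoring."""
    return make_ds([1, 2, 3, 4], [1, 1, 1, 1], group=["X", "X", "Y", "Y"])
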