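import numpy as np
import pandas as pd
import pytest

from actidep import build_matrix, simulate_cohort
from actidep.io import CONTROL, MINUTES_PER_DAY, SubjectSeries
from actidep.simulate import SimulationConfig


def make_series(
    subject_id: str = "s1",
    group: int = CONTROL,
    n_days: int = 1,
    start: str = "2020-01-06",
    drop_minutes: tuple[int, ...] = (),
    extra_minutes: int = 0,
    seed: int = 0,
) -> SubjectSeries:
    """Hand-rolled series: ``n_days`` complete days, optionally with dropped
    minute slots (making days partial) and a trailing partial day."""
    rng = np.random.default_rng(seed)
    n = n_days * MINUTES_PER_DAY + extra_minutes
    ts = pd.date_range(start=start, periods=n, freq="min")
    frame = pd.DataFrame(
        {
            "timestamp": ts,
            "date": ts.date,
            "activity": rng.integers(0, 500, size=n),
        }
    )
    if drop_minutes:
        frame = frame.drop(index=list(drop_minutes)).reset_index(drop=True)
    return SubjectSeries(subject_id=subject_id, group=group, frame=frame)


@pytest.fixture(scope="session")
def study_cohort():
    """The default study-sized cohort: 32 control + 23 condition, 7 days."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def study_dataset(study_cohort):
    return build_matrix(study_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for pipeline-level tests: 6 control + 4 condition."""
    return simulate_cohort(SimulationConfig(n_control=6, n_condition=4, seed=11))
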