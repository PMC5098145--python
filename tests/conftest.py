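import numpy as np
import pytest

from prognosig import SurvivalData, table1_fixture


@pytest.fixture(scope="session")
def table1():
    """The packaged 37-variable reference signature."""
    return table1_fixture()


def random_cohort(rng: np.random.Generator, n: int, *, censor_frac: float = 0.3, ties: bool = False):
    """A small random right-censored cohort for cross-checks."""
    if ties:
        times = rng.integers(1, 15, n).astype(float)
    else:
        times = rng.exponential(10.0, n) + 0.01
    events = (rng.uniform(size=n) > censor_frac).astype(int)
    if events.sum() == 0:
        events[int(rng.integers(0, n))] = 1
    return SurvivalData(times=times, events=events)
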