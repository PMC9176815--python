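import numpy as np
import pytest

from pgd import BeliefTable, PgdParams, make_schedule, run_session


@pytest.fixture(scope="session")
def belief_table() -> BeliefTable:
    return BeliefTable(t_max=15, p=0.5)


@pytest.fixture(scope="session")
def periodic_session():
    """One medium periodic-schedule PGD session reused across analysis tests."""
    schedule = make_schedule("periodic", n_trials=2400, t_block=300)
    log = run_session(schedule, PgdParams(), seed=1, record_filters=True)
    return log, schedule


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
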