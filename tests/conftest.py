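import numpy as np
import pandas as pd
import pytest

from attnorm.pipeline import make_fixture
from attnorm.task_core import STANDARD_CUE_SET, enumerate_block_conditions


@pytest.fixture(scope="session")
def tiny_session():
    """Deterministic 2-block, 6-neuron session used across test modules."""
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def conditions():
    return enumerate_block_conditions(STANDARD_CUE_SET)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_deterministic_spikes(rates_by_trial, window=(0.0, 1000.0), neuron_id="n0"):
    """Evenly spaced spike trains with exact windowed rates (spikes/s)."""
    rows = []
    t0, t1 = window
    dur_s = (t1 - t0) / 1000.0
    for trial_id, rate in rates_by_trial.items():
        n = int(round(rate * dur_s))
        if n:
            times = t0 + (np.arange(n) + 0.5) * (t1 - t0) / n
            rows.append(
                pd.DataFrame({"neuron_id": neuron_id, "trial_id": trial_id, "t_ms": times})
            )
    if not rows:
        return pd.DataFrame(columns=["neuron_id", "trial_id", "t_ms"])
    return pd.concat(rows, ignore_index=True)
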