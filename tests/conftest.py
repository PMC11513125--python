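"""Shared fixtures for the optoburst test suite."""

import numpy as np
import pytest

from optoburst import (
    DurationResponse,
    HillResponse,
    TimeGrid,
    TraceSetConfig,
    gen_trace_set,
)


@pytest.fixture(scope="session")
def grid():
    return TimeGrid()


@pytest.fixture(scope="session")
def kon_true():
    return HillResponse(kon0=2.8, K_D=3.7, H=6.1)


@pytest.fixture(scope="session")
def koff_true():
    return DurationResponse(koff_base=2.0, koff_floor=1.54, K_D_off=3.7, H_off=6.1)


@pytest.fixture(scope="session")
def small_trace_set():
    """20 nuclei per condition: enough for analysis smoke tests, fast."""
    df, ledger = gen_trace_set(TraceSetConfig(), n_nuclei=20, seed=101)
    return df, ledger


@pytest.fixture(scope="session")
def medium_trace_set():
    """60 nuclei per condition, used by the inference tests."""
    df, ledger = gen_trace_set(TraceSetConfig(), n_nuclei=60, seed=11)
    return df, ledger


@pytest.fixture
def rng():
    return np.random.default_rng(0)
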