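import numpy as np
import pytest

from paintmap import SignalThresholds, call_signals
from paintmap.datasets import (
    load_sorghum_mcp_counts,
    load_tripidium_karyotype,
    synthetic_signal_patterns,
)


@pytest.fixture(scope="session")
def table1():
    """The published 10x10 probe-set x chromosome count matrix."""
    return load_sorghum_mcp_counts()


@pytest.fixture(scope="session")
def table2():
    """The published karyotype table (arm means/SDs in micrometres)."""
    return load_tripidium_karyotype()


@pytest.fixture(scope="session")
def table1_calls(table1):
    """Default-threshold signal calls over the published matrix, with
    synthetic stand-in morphology patterns for candidate cells."""
    profile = synthetic_signal_patterns(table1)
    return call_signals(table1, SignalThresholds(), profile)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
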