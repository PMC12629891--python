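import numpy as np
import pytest

from fpdbg import (
    BGModel,
    DetectorConfig,
    ReadoutModel,
    TimingConfig,
    build_timeline,
)


@pytest.fixture(scope="session")
def small_det() -> DetectorConfig:
    """A 64x64 panel without hot pixels for fast unit tests."""
    return DetectorConfig(n_rows=64, n_cols=64, hot_pixels=())


@pytest.fixture(scope="session")
def timing() -> TimingConfig:
    return TimingConfig()


@pytest.fixture(scope="session")
def bg() -> BGModel:
    return BGModel()


@pytest.fixture(scope="session")
def rolling() -> ReadoutModel:
    return ReadoutModel(scheme="rolling_periphery_to_center")


@pytest.fixture(scope="session")
def global_readout() -> ReadoutModel:
    return ReadoutModel(scheme="global")


@pytest.fixture(scope="session")
def two_spill_timeline(timing):
    """Two 1-s spills separated by a 0.5-s pause, session starting at t=0."""
    return build_timeline(timing, [(1.0, 0.5), (1.0, 0.5)], session_start=0.0)
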