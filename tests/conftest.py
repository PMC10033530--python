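"""Shared fixtures: model defaults, toy grids, and the full study sweep."""

import time

import numpy as np
import pytest

from regenfit import GridSpec, ModelParameters, classify, run_sweep
from regenfit.synthetic_data import STUDY_TIMES

#: the study's post-PHx observation schedule (hours)
OBS_TIMES = tuple(t for t in STUDY_TIMES if t >= 0)


@pytest.fixture(scope="session")
def default_params():
    return ModelParameters()


@pytest.fixture(scope="session")
def toy_sweep(default_params):
    """A fast 5x5 sweep for unit tests that only need plumbing."""
    return run_sweep(GridSpec(n_M=5, n_Kcd=5), default_params, OBS_TIMES)


@pytest.fixture(scope="session")
def full_sweep_timed(default_params):
    """The full 100x100 study sweep plus its wall-clock build time."""
    t0 = time.perf_counter()
    sweep = run_sweep(GridSpec(), default_params, OBS_TIMES)
    return sweep, time.perf_counter() - t0


@pytest.fixture(scope="session")
def full_sweep(full_sweep_timed):
    return full_sweep_timed[0]


@pytest.fixture(scope="session")
def full_modes(full_sweep):
    return classify(full_sweep)
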