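import numpy as np
import pytest

import adaptgait as ag
from adaptgait.signal_io import load_sign_map, normalize_side


@pytest.fixture(scope="session")
def sign_map():
    return load_sign_map()


@pytest.fixture(scope="session")
def cohort():
    return ag.make_cohort(4, seed=101)


@pytest.fixture(scope="session")
def small_recording(cohort, sign_map):
    """A short right-side session, already side-normalized."""
    rec = ag.simulate_subject(cohort[1], ag.SessionSpec(n_strides=25), 1, seed=7)
    return normalize_side(rec, sign_map)


@pytest.fixture(scope="session")
def left_recording(cohort):
    """Raw (device-frame) session from the left-side subject."""
    return ag.simulate_subject(cohort[0], ag.SessionSpec(n_strides=15), 1, seed=8)
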