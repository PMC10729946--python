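"""Shared fixtures: the settled single-spiral state and derived recordings.

The spiral is expensive to create, so it is built once per session and every
test works on copies.
"""

import numpy as np
import pytest

from optospiral.cellmodels import ChR2Params, IonicParams
from optospiral.tissue import TissueParams, init_spiral, integrate


@pytest.fixture(scope="session")
def tissue_params():
    return TissueParams()


@pytest.fixture(scope="session")
def ionic_params():
    return IonicParams()


@pytest.fixture(scope="session")
def chr2_params():
    return ChR2Params()


@pytest.fixture(scope="session")
def settled_spiral(tissue_params):
    """A single spiral settled for 600 ms; tests must copy before advancing."""
    return init_spiral(tissue_params, settle_time=600.0)


@pytest.fixture(scope="session")
def spiral_recording(settled_spiral, tissue_params):
    """150 ms of free rotation at 1 kHz frames, starting from the settled state."""
    return integrate(settled_spiral.copy(), tissue_params, duration=150.0,
                     frame_interval=1.0)
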