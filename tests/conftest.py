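"""Shared fixtures: small phantoms and designs generated at test time."""

import numpy as np
import pytest

from mocolab.containers import PhantomSpec, TaskDesign
from mocolab.synthetic import default_localizer_roi, generate_phantom


@pytest.fixture
def empty_design():
    """A 12-volume design with a declared condition but no events."""
    return TaskDesign(conditions=["a"], events=[], run_length=12, tr=1.0)


@pytest.fixture
def block_design():
    """A compact 80-volume two-condition block design for fast GLM tests."""
    events = []
    for k in range(4):
        t0 = 8.0 + 18.0 * k
        events.append(("static", t0, 6.0))
        events.append(("moving", t0 + 9.0, 6.0))
    return TaskDesign(conditions=["static", "moving"], events=events,
                      run_length=80, tr=1.0)


@pytest.fixture
def small_phantom(block_design):
    """16³ phantom with one 2% 'moving' ROI, 1% noise; returns (bold, truth, spec)."""
    spec = PhantomSpec(
        shape=(16, 16, 16), n_volumes=block_design.run_length,
        activation_rois=[default_localizer_roi((16, 16, 16))], seed=7,
    )
    bold, truth = generate_phantom(spec, block_design)
    return bold, truth, spec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
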