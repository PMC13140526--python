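import numpy as np
import pytest

from colhtl.cohort import ParticipantState


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def swimmer():
    """A fixed well-trained subject used as ground truth across tests."""
    return ParticipantState(
        id="P01",
        sex="M",
        body_mass=82.0,
        true_hbmass=940.4,
        true_hb_conc=156.0,
        true_hct=0.46,
        true_k=3.0,
        lactate_a=4.0 * np.exp(-11.0 * 1.4),
        lactate_b=11.0,
        baseline_cohb=1.0,
    )
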