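import numpy as np
import pytest

from relaxkit.datatypes import RelaxationRecord, ResidueId
from relaxkit.modelfree import DiffusionModel, MFParams, forward_rates


@pytest.fixture
def iso_diff():
    """Isotropic tumbling at the study's overall correlation time."""
    return DiffusionModel(kind="isotropic", tau_m=9.6)


@pytest.fixture
def rigid_record(iso_diff):
    """A noise-free observable triple generated from model 1 (S2 = 0.85)."""
    r1, r2, noe = forward_rates(MFParams(S2=0.85), iso_diff)
    return RelaxationRecord(
        ResidueId(1), r1, 0.01 * r1, r2, 0.01 * r2, noe, 0.01
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
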