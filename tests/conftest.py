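import numpy as np
import pytest

from stalkmech.synthetic_data import (
    HelixSpec,
    MotionSpec,
    make_aform_helix,
    make_two_domain_system,
)


@pytest.fixture(scope="session")
def straight_helix():
    """Ideal 20-bp duplex with its base-pair list (session-wide, read-only)."""
    return make_aform_helix(HelixSpec(n_bp=20))


@pytest.fixture(scope="session")
def two_domain_26():
    """Two-domain system with a noiseless imposed 26.5 degree rotation."""
    return make_two_domain_system(
        HelixSpec(n_bp=16),
        HelixSpec(n_bp=12),
        MotionSpec(angle=26.5, axis_direction=(0.0, 0.0, 1.0), axis_origin=(3.0, 2.0, 40.0)),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
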