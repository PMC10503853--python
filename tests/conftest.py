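import numpy as np
import pytest

from fluorotherm.fieldgen import FieldSpec, generate_pipe_field
from fluorotherm.presets import dataset1_calibration, dataset2_calibration


@pytest.fixture(scope="session")
def cal5():
    """Five-band sharp-edge calibration spanning 296-314 K."""
    return dataset1_calibration()


@pytest.fixture(scope="session")
def cal6():
    """Six-filter soft-edge calibration spanning 288-382 K."""
    return dataset2_calibration()


@pytest.fixture(scope="session")
def pipe_field():
    """A 32x32 annulus conduction field inside 298-308 K."""
    spec = FieldSpec(
        "pipe_cross_section",
        (32, 32),
        {"r_inner": 5.0, "r_outer": 14.0, "t_inner": 307.0, "t_outer": 299.0},
        (298.0, 308.0),
    )
    return generate_pipe_field(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
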