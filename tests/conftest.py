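import numpy as np
import pytest
from hypothesis import settings

from nirsasym import Montage, build_schedule, load_montage

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clinical_montage():
    return load_montage("clinical28")


@pytest.fixture(scope="session")
def healthy_montage():
    return load_montage("healthy33")


@pytest.fixture(scope="session")
def tiny_montage():
    """One homotopic pair - enough for fast forward-model tests."""
    return Montage(
        name="tiny",
        channels=["C3-CP3", "C4-CP4"],
        hemisphere_of_channel={"C3-CP3": "left", "C4-CP4": "right"},
        symmetric_pairs=[("C3-CP3", "C4-CP4")],
    )


@pytest.fixture(scope="session")
def clinical_schedule():
    return build_schedule("clinical", n_blocks=4, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
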