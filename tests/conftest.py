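import pytest

from t1require import ReferenceParams, SpinEchoParams, make_phantom


@pytest.fixture(scope="session")
def refs():
    return ReferenceParams()


@pytest.fixture(scope="session")
def se_params():
    return SpinEchoParams(tr=525.0, te=10.0)


@pytest.fixture(scope="session")
def homogeneous_phantom():
    """64³ phantom with every voxel exactly at the tissue means."""
    return make_phantom((64, 64, 64), seed=7, heterogeneity=0.0)


@pytest.fixture(scope="session")
def hetero_phantom():
    """64³ phantom with full literature heterogeneity."""
    return make_phantom((64, 64, 64), seed=11, heterogeneity=1.0)
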