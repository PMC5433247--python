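import numpy as np
import pytest

from pcorrnet import CommonDriverSpec, GroundTruthNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def common_driver_gt():
    """The 1 -> 2, 1 -> 3 ground truth of the common-driver network."""
    return GroundTruthNetwork.from_edges(3, [(0, 1), (0, 2)])


@pytest.fixture
def weak_driving_spec():
    return CommonDriverSpec.from_case(2, n_samples=1000, n_subjects=50, base_seed=0)
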