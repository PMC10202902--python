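import numpy as np
import pytest

import trialcube as tc


@pytest.fixture
def melanoma():
    return tc.load_fixture("melanoma_association")


@pytest.fixture
def vem_initial():
    return tc.load_fixture("vemurafenib_initial")


@pytest.fixture
def vem_adapted():
    return tc.load_fixture("vemurafenib_adapted")


@pytest.fixture
def toy_2x2x1():
    """Two biomarkers x two treatments x one classifier, fully active."""
    return tc.build_space(
        [
            tc.create_axis("B", "biomarker", ["b1", "b2"]),
            tc.create_axis("T", "treatment", ["t1", "t2"]),
            tc.create_axis("C", "classifier", ["c1"]),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230522)
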