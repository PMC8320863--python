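import numpy as np
import pytest

import glogseed as gs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def easy_fixture():
    """One easy synthetic image (well-separated dark nuclei) plus ground truth."""
    cfg = gs.SynthConfig(rng_seed=7, n_nuclei=12)
    img, gt = gs.generate_image(cfg)
    return img, gt


@pytest.fixture(scope="session")
def default_bank():
    return gs.build_glog_filter_bank()
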