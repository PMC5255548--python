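import numpy as np
import pytest

import labfuse as lf


@pytest.fixture(scope="session")
def cmap():
    return lf.build_colormap("equal_lightness")


@pytest.fixture(scope="session")
def phantom():
    return lf.make_prostate_phantom(lf.PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def fused(phantom, cmap):
    channels = [
        lf.preprocess_channel(c, phantom["t2"], lf.PROSTATE_CONFIG) for c in phantom["channels"]
    ]
    return lf.fuse_channels(*channels, cmap)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
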