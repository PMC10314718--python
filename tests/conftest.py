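import numpy as np
import pytest

from simbench.clb import CLBConfig, CLBLayerParams, GrayMapping


@pytest.fixture(scope="session")
def fast_layer():
    """Small, quick-to-render CLB layer for unit tests."""
    return CLBLayerParams(
        mean_cluster_count=40,
        mean_blobs_per_cluster=10,
        cluster_spread=6.0,
        blob_length_x=4.0,
        blob_length_y=2.0,
        blob_alpha=2.3,
        blob_beta=0.8,
    )


@pytest.fixture(scope="session")
def fast_config(fast_layer):
    return CLBConfig(
        layers=(fast_layer,),
        image_size=96,
        gray_mapping=GrayMapping(offset=0.0, scale=60.0, clip_low=0.0, clip_high=255.0),
        config_name="fast-test",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
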