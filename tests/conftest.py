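import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_tissue_field():
    """A modest clean field shared by segmentation/quantification tests."""
    from acidoquant.synthetic_data import (
        ChannelSpec,
        CountDistribution,
        TissueSimConfig,
        simulate_tissue_field,
    )

    cfg = TissueSimConfig(
        n_cells=50,
        field_size_px=(640, 640),
        seed=11,
        channels=(ChannelSpec("PACC1", 1.0, CountDistribution("constant", 5)),),
        noise_sd=0.0,
        background_level=0.0,
    )
    return simulate_tissue_field(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
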