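import numpy as np
import pytest

from portalwatch.simulate import DeliverySpec, ErrorSpec, PanelGeometry


@pytest.fixture(scope="session")
def small_geometry() -> PanelGeometry:
    """A reduced panel that keeps simulator tests fast."""
    return PanelGeometry(n_pixels=96)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_spec(**kw) -> DeliverySpec:
    defaults = dict(patient_id="P1", n_segments=30, seed=7, noise_sd=0.0)
    defaults.update(kw)
    return DeliverySpec(**defaults)


@pytest.fixture()
def noiseless_spec() -> DeliverySpec:
    return make_spec()


@pytest.fixture()
def mu10_spec() -> DeliverySpec:
    return make_spec(error=ErrorSpec("mu_increase", 10))
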