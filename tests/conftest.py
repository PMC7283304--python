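import numpy as np
import pytest

from ctperf.phantom import AIFSpec, PhantomSpec, evaluate_aif


@pytest.fixture(scope="session")
def default_aif_spec() -> AIFSpec:
    return AIFSpec()


@pytest.fixture(scope="session")
def times() -> np.ndarray:
    return np.arange(30) * 2.0


@pytest.fixture(scope="session")
def aif_curve(default_aif_spec, times) -> np.ndarray:
    return evaluate_aif(default_aif_spec, times)


@pytest.fixture()
def noiseless_spec() -> PhantomSpec:
    return PhantomSpec(noise_sd=0.0)


@pytest.fixture(scope="session")
def default_region_params() -> list[tuple[float, float]]:
    """(CBF, MTT) of the default normal / penumbra / core compartments."""
    return [(60.0, 4.0), (25.0, 7.0), (8.0, 10.0)]
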