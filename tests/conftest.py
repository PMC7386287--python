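import numpy as np
import pytest

from chloropix import AssayConfig, RenderConfig, render_flask_image, simulate_calibration_dataset


@pytest.fixture(scope="session")
def render_config():
    return RenderConfig(seed=7)


@pytest.fixture(scope="session")
def rendered_photo(render_config):
    """One mid-concentration rendered flask photograph with ground truth."""
    return render_flask_image(8.0, render_config, rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def simulated_assay():
    """Default-condition simulated calibration dataset (seed 42)."""
    return simulate_calibration_dataset(AssayConfig(seed=42))
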