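import numpy as np
import pytest

from synoquant import RegionClass, RegionLabelMap, scenario_presets
from synoquant.synthetic import generate_section, render_channels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_labels():
    """100x200 map entirely SI_N at 10 um/px: 2 mm^2 of tissue."""
    labels = np.full((100, 200), int(RegionClass.SI_N), dtype=np.uint8)
    return RegionLabelMap(labels=labels, pixel_size_um=10.0)


@pytest.fixture(scope="session")
def ctrl_scenario():
    return scenario_presets()["CTRL"]


@pytest.fixture(scope="session")
def ctrl_section(ctrl_scenario):
    return generate_section(ctrl_scenario, rng_seed=7)


@pytest.fixture(scope="session")
def ctrl_image(ctrl_scenario, ctrl_section):
    return render_channels(ctrl_section, ctrl_scenario, rng_seed=8, sample_id="CTRL-x")
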