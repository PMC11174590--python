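import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the `oracles` helper module

from canopyhydra.types import SceneConfig, TreatmentDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20240529)


@pytest.fixture
def small_design():
    """One season, one replicate: nine plots — fast to render."""
    return TreatmentDesign(replicates=1, seasons=1)


@pytest.fixture
def small_scene_config():
    return SceneConfig(plot_size_px=(16, 16), seed=7)


@pytest.fixture
def small_scene(small_design, small_scene_config):
    from canopyhydra.synthetic_scene import simulate

    scene, table = simulate(small_design, small_scene_config)
    return scene, table
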