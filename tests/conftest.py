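import numpy as np
import pytest

from bassdet.synthetic import EASY_PRESET, TINY_PRESET, generate_scene


@pytest.fixture(scope="session")
def tiny_scene():
    """One deterministic 160x160 tank scene with five fish."""
    return generate_scene(TINY_PRESET.replace(seed=3), source_id="tiny3")


@pytest.fixture(scope="session")
def easy_scenes():
    """Eight deterministic easy scenes (training-smoke conditions)."""
    return [generate_scene(EASY_PRESET.replace(seed=100 + i), source_id=f"e{i}")
            for i in range(8)]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
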