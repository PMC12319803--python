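import numpy as np
import pytest

from tacsalpha import EffectSpec, StudyDesign, generate_participant, grid_layout


@pytest.fixture(scope="session")
def small_design():
    """Full-protocol design on a single 10 s block (keeps tests quick)."""
    return StudyDesign(blocks=("train10",))


@pytest.fixture(scope="session")
def small_layout():
    return grid_layout(3, 3, somatosensory=(slice(0, 3), slice(0, 3)))


@pytest.fixture(scope="session")
def small_recording(small_design, small_layout):
    """One seeded participant (both sessions, one block, 3x3 units)."""
    spec = EffectSpec(isf=10.0, effect_units=tuple(range(9)), seed=7)
    return generate_participant(small_design, small_layout, spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
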