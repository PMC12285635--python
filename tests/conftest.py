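import numpy as np
import pytest

from natfactor import PhantomSpec, filament_phantom


@pytest.fixture(scope="session")
def filament_corpus():
    """Ten default filament phantoms (the natural-like regime)."""
    return [filament_phantom(PhantomSpec(seed=s)) for s in range(10)]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
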