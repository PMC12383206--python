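import numpy as np
import pytest

from cardiacdiff.phantoms import PhantomSpec, generate_dataset, generate_phantom


@pytest.fixture(scope="session")
def toy_spec():
    return PhantomSpec(grid_size=32)


@pytest.fixture(scope="session")
def toy_dataset(toy_spec):
    """30 phantoms at 32x32, split 21/3/6."""
    return generate_dataset(30, toy_spec, seed=5)


@pytest.fixture(scope="session")
def canonical_masks(toy_spec):
    return [generate_phantom(PhantomSpec(grid_size=32, seed=s)).mask for s in range(4)]
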