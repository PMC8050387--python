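import numpy as np
import pytest

from neuritequant import SyntheticSpec, generate_field


@pytest.fixture(scope="session")
def demo_field():
    """A small mixed field: 8 nuclei with somata, 4 neurites."""
    spec = SyntheticSpec(field_shape=(256, 256), n_nuclei=8, n_neurites=4, seed=42)
    return generate_field(spec)


@pytest.fixture(scope="session")
def nuclei_only_field():
    """A field with 10 disjoint nuclei and no neurites, SNR 10."""
    spec = SyntheticSpec(field_shape=(256, 256), n_nuclei=10, n_neurites=0, snr=10, seed=7)
    return generate_field(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
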