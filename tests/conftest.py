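import numpy as np
import pytest

from trabfe.io_stack import ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def random_stack(shape, p=0.5, seed=0, pixel_size=36.0, slice_increment=36.0):
    """Seeded random binary stack; shape = (n_slices, ny, nx)."""
    r = np.random.default_rng(seed)
    return ImageStack(
        slices=(r.random(shape) < p).astype(np.uint8),
        pixel_size=pixel_size,
        slice_increment=slice_increment,
    )
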