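import numpy as np
import pytest

from kdentropy.gridding import Sample1D, bin_samples, make_grid
from kdentropy.bandwidth import select_bandwidth


@pytest.fixture
def gaussian_binned():
    """A standard-normal sample binned on a padded 1024-bin grid, with its
    selected bandwidth — the common starting point for density tests."""
    sample = Sample1D(np.random.default_rng(0).normal(0.0, 1.0, 1000))
    grid = make_grid(sample, 1024)
    binned = bin_samples(sample, grid)
    return sample, grid, binned, select_bandwidth(binned)
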