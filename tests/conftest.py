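import warnings

import numpy as np
import pytest

from isletpol.instance_seg import filter_instances, instance_segment
from isletpol.synthetic import SynthParams, generate_islet


@pytest.fixture(scope="session")
def default_islet():
    """One full-size synthetic plane under default study conditions."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_islet(SynthParams(seed=2))


@pytest.fixture(scope="session")
def default_labels(default_islet):
    """Watershed instances of the default plane after the >490 px filter."""
    return filter_instances(instance_segment(default_islet.semantic_mask()), 490)


@pytest.fixture(scope="session")
def clean_islet():
    """Noise-free, speckle-free plane with enrichment ratio 1.5."""
    params = SynthParams(
        seed=7,
        enrichment_ratio=1.5,
        noise_sd=0.0,
        granule_density=0,
        insulin_cell_cv=0.0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_islet(params)


def random_blob_mask(rng: np.random.Generator, size: int = 32, n_discs: int = 3) -> np.ndarray:
    """Small random multi-disc mask for oracle comparisons."""
    mask = np.zeros((size, size), dtype=bool)
    yy, xx = np.ogrid[:size, :size]
    for _ in range(n_discs):
        r, c = rng.integers(4, size - 4, 2)
        rad = rng.integers(2, size // 4)
        mask |= (yy - r) ** 2 + (xx - c) ** 2 <= rad**2
    return mask
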