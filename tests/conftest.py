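import warnings

import numpy as np
import pandas as pd
import pytest

import droptex
from droptex.gam import slice_tables


def random_quantized(rng, size_lo=5, size_hi=8, n_levels_hi=6, masked=True):
    """A random small QuantizedROI for oracle comparisons."""
    h = int(rng.integers(size_lo, size_hi + 1))
    w = int(rng.integers(size_lo, size_hi + 1))
    n_levels = int(rng.integers(2, n_levels_hi + 1))
    frame = rng.integers(0, n_levels, size=(h, w)).astype(np.uint8)
    if masked:
        mask = rng.random((h, w)) < 0.8
        if not mask.any():
            mask[h // 2, w // 2] = True
    else:
        mask = np.ones((h, w), dtype=bool)
    return droptex.quantize(frame, mask, bin_width=1)


@pytest.fixture(scope="session")
def small_dataset():
    """Five synthetic droplet movies at reduced size, shared across tests."""
    cfg = droptex.make_default_config(7, n_frames=100, frame_size=64)
    return cfg, droptex.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_feature_table(small_dataset):
    _, dataset = small_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tables = [droptex.extract_feature_table(s) for s in dataset]
    return pd.concat(tables, ignore_index=True)


@pytest.fixture(scope="session")
def small_slices(small_feature_table):
    return slice_tables(small_feature_table)
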