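"""Shared fixtures: small codebooks and simulated fields."""

import numpy as np
import pytest

import fishcoder as fc


@pytest.fixture(scope="session")
def small_codebook() -> fc.Codebook:
    """10 genes on an 8-round x 2-channel space."""
    return fc.assign_barcodes(
        [f"g{i}" for i in range(10)], n_rounds=8, n_channels=2, rng_seed=0
    )


@pytest.fixture(scope="session")
def small_field(small_codebook):
    """A 192x192 field with 6 cells, rendered without dropout."""
    fs = fc.FieldSpec(
        height=192,
        width=192,
        n_cells=6,
        cell_radius_range=(8, 12),
        expression_means={g: 2.0 for g in small_codebook.genes()},
    )
    truth = fc.simulate_field(fs, small_codebook, rng_seed=1)
    acq = fc.AcquisitionSpec(rng_seed=2, dropout_rate=0.0, false_spot_rate=0.0)
    stack = fc.render_stack(truth, small_codebook, acq)
    return truth, stack


def render_single_spot(shape=(64, 64), y=32.0, x=32.0, sigma=1.3, amp=1000.0):
    """One noise-free Gaussian spot on a dark plane."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    g = amp * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2)) / (
        2 * np.pi * sigma**2
    )
    return g
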