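"""Shared fixtures: small seeded cohorts and processed tensors.

Everything is generated programmatically; sizes are kept small so the whole
suite runs on one CPU.  Session-scoped fixtures are shared across test
modules to avoid re-simulating.
"""

from __future__ import annotations

import numpy as np
import pytest

from atlaspd.design import BlockDesign
from atlaspd.preprocess import build_dataset
from atlaspd.synthgen import GroupEffectProfile, NoiseProfile, simulate_cohort


@pytest.fixture(scope="session")
def design_10hz() -> BlockDesign:
    return BlockDesign(sampling_hz=10.0)


@pytest.fixture(scope="session")
def noiseless_cohort(design_10hz):
    return simulate_cohort(1, design=design_10hz,
                           effects=GroupEffectProfile.high_snr(),
                           noise=NoiseProfile.zero(), seed=1)


@pytest.fixture(scope="session")
def small_cohort(design_10hz):
    """Six subjects with mild noise: exercises the full chain quickly."""
    return simulate_cohort(2, design=design_10hz,
                           effects=GroupEffectProfile.high_snr(),
                           noise=NoiseProfile.low(), seed=5)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return build_dataset(small_cohort, chromophore="hbo", target_hz=1.0, seed=5)


@pytest.fixture(scope="session")
def toy_sequences():
    """Separable three-class (N, C, T) toy tensor for fast model tests."""
    rng = np.random.default_rng(0)
    n_per, c, t = 12, 6, 60
    y = np.repeat(["HC", "HY1", "HY2"], n_per)
    x = rng.standard_normal((3 * n_per, c, t)).astype(np.float32) * 0.3
    wave = np.sin(np.linspace(0, 4 * np.pi, t))
    for i, lab in enumerate(y):
        amp = {"HC": 1.0, "HY1": -1.0, "HY2": 0.0}[lab]
        x[i, :2] += amp * wave
        if lab == "HY2":
            x[i, 2:4] += wave
    return x, y
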