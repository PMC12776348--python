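"""Shared fixtures: small catalogs and seeded random models."""

import numpy as np
import pytest

from mhnet import Dataset, EventCatalog, MutualHazardNetwork


def make_catalog(n: int) -> EventCatalog:
    return EventCatalog([f"E{i}" for i in range(n)])


def random_model(n: int, seed: int, scale: float = 0.8,
                 kind: str = "observation_aware") -> MutualHazardNetwork:
    rng = np.random.default_rng(seed)
    return MutualHazardNetwork(rng.normal(0.0, scale, (n + 1, n)), make_catalog(n), kind)


def random_dataset(n: int, N: int, seed: int) -> Dataset:
    rng = np.random.default_rng(seed)
    return Dataset(rng.integers(0, 2, (N, n)), make_catalog(n))


@pytest.fixture
def cat3() -> EventCatalog:
    return make_catalog(3)


@pytest.fixture
def zero2() -> MutualHazardNetwork:
    """Two events, all parameters zero (every rate equals 1)."""
    return MutualHazardNetwork.zeros(make_catalog(2))
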