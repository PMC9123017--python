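"""Shared fixtures: small synthetic worlds and deterministic RNGs."""

from __future__ import annotations

import numpy as np
import pytest

from jumbophage import synthetic


@pytest.fixture(scope="session")
def small_world() -> synthetic.SyntheticWorld:
    """A compact clean world reused by read-only tests."""
    cfg = synthetic.WorldConfig(
        n_clusters=3,
        genomes_per_cluster=4,
        population_size=2,
        length_range=(200_000, 260_000),
        genes_per_genome=60,
        families_per_cluster=40,
        n_coverage_samples=20,
        n_stations=8,
    )
    return synthetic.make_world(cfg, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
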