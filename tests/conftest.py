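import numpy as np
import pandas as pd
import pytest

from betascape import synth


@pytest.fixture(scope="session")
def small_world():
    """A compact world for unit tests: 16x16, 3 env vars, 3 classes."""
    return synth.generate_world(
        extent=(-8.0, 32.0, 8.0, 48.0), grid_shape=(16, 16), n_env_vars=3, n_classes=3, seed=7
    )


@pytest.fixture(scope="session")
def small_pool(small_world):
    return synth.generate_species_pool(small_world, n_species=25, seed=8)


@pytest.fixture(scope="session")
def small_occurrences(small_world, small_pool):
    effort = synth.two_patch_effort(small_world)
    return synth.sample_occurrences(small_world, small_pool, effort, 6000, seed=9)


def random_community(rng, n_sites, n_species, sparsity=0.4):
    """Random abundance table with no empty sites."""
    counts = rng.poisson(3.0, size=(n_sites, n_species))
    counts[rng.random(counts.shape) < sparsity] = 0
    empty = counts.sum(axis=1) == 0
    counts[empty, rng.integers(0, n_species, int(empty.sum()))] = 1
    return counts.astype(float)
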