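import numpy as np
import pytest

from cardioquant import (
    ImageSimConfig,
    TrackSimConfig,
    simulate_image_fields,
    simulate_tracks,
)


def random_track_values(rng, n_chroms=3, max_bins=200):
    """Random sparse non-negative bin arrays for round-trip tests."""
    values = {}
    for i in range(rng.integers(1, n_chroms + 1)):
        n = int(rng.integers(1, max_bins))
        arr = rng.random(n) * 10
        arr[rng.random(n) < 0.5] = 0.0  # sparse, exercises run splitting
        values[f"chr{i + 1}"] = arr
    return values


@pytest.fixture(scope="session")
def small_track_sim():
    """A reduced two-condition coverage simulation shared across tests."""
    cfg = TrackSimConfig(
        n_genes=60,
        genes_per_chromosome=20,
        depth=400_000,
        seed=11,
    )
    return simulate_tracks(cfg)


@pytest.fixture(scope="session")
def default_track_sim():
    """The study-condition simulation: 200 genes, 20% enriched at fold 2,
    1M reads per condition, Poisson noise."""
    return simulate_tracks(TrackSimConfig(seed=7))


@pytest.fixture(scope="session")
def image_sim():
    """Five noisy synthetic fields plus ground truth."""
    fields, gt = simulate_image_fields(ImageSimConfig(seed=5), n_fields=5)
    return fields, gt


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
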