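import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from bovintro import HaplotypePanel, PopulationMap


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_panel(
    rng: np.random.Generator,
    n_samples: int = 6,
    n_sites: int = 40,
    contig_length: int = 100_000,
    missing_rate: float = 0.0,
    prefix: str = "s",
) -> HaplotypePanel:
    """Small random diploid panel for unit fixtures."""
    positions = np.sort(rng.choice(contig_length, size=n_sites, replace=False))
    alleles = rng.integers(0, 2, size=(2 * n_samples, n_sites)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(alleles.shape) < missing_rate
        alleles[mask] = -1
    return HaplotypePanel(
        alleles, positions, "1", [f"{prefix}{i}" for i in range(n_samples)], contig_length
    )


@pytest.fixture
def small_panel(rng):
    return random_panel(rng)


@pytest.fixture
def two_pop_map():
    return PopulationMap({f"a{i}": "A" for i in range(5)} | {f"b{i}": "B" for i in range(5)})
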