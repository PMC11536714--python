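import numpy as np
import pytest

from recmt.pedigree import Pedigree
from recmt.simdata import SimulationConfig, simulate_pedigree


def random_spd(m: int, rng, scale: float = 1.0) -> np.ndarray:
    """Well-conditioned random SPD matrix."""
    A = rng.standard_normal((m, m))
    return scale * (A @ A.T + m * np.eye(m))


@pytest.fixture
def rng():
    return np.random.default_rng(20240502)


@pytest.fixture
def trio():
    """Two unrelated founders and their offspring."""
    return Pedigree(labels=("1", "2", "3"),
                    sire=np.array([-1, -1, 0]), dam=np.array([-1, -1, 1]))


@pytest.fixture
def small_pedigree():
    """~50 individuals, 4 discrete generations, random mating."""
    cfg = SimulationConfig(n_founders=14, n_generations=3, n_per_generation=12,
                           n_records=10, seed=7)
    return simulate_pedigree(cfg)
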