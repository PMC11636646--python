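import numpy as np
import pytest

from dartfdr import SimulationConfig, run_benchmark
from dartfdr.datasets import toy_example

# master seed for every replicated statistical check in the suite
SUITE_SEED = 0


@pytest.fixture()
def toy():
    return toy_example()


@pytest.fixture(scope="session")
def se1_benchmark():
    """200-replicate reference-design benchmark at the four nominal levels."""
    return run_benchmark(
        SimulationConfig(),
        alphas=(0.05, 0.1, 0.15, 0.2),
        n_reps=200,
        seed=SUITE_SEED,
    )


@pytest.fixture(scope="session")
def switched_benchmark():
    """Same design with 6% of alternatives label-switched with nulls."""
    return run_benchmark(
        SimulationConfig(tau=0.06),
        alphas=(0.05,),
        n_reps=200,
        seed=SUITE_SEED,
        methods=("dart",),
    )


def random_distance_matrix(rng: np.random.Generator, m: int):
    """Random Euclidean distance matrix from 2-D points (helper)."""
    from dartfdr import DistanceMatrix

    pts = rng.normal(size=(m, 2)) * rng.uniform(0.5, 2.0)
    ids = [f"h{i}" for i in range(m)]
    return DistanceMatrix.from_coordinates(ids, pts)
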