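import numpy as np
import pandas as pd
import pytest

from nanorf import (
    SimConfig,
    ComplexSpec,
    simulate_dataset,
    compute_dependence,
    impute_missing,
)


def small_sim_config(seed: int = 11, missing_rate: float = 0.05) -> SimConfig:
    return SimConfig(
        n_proteins=300,
        conditions=(("A", 2), ("B", 2), ("C", 3)),
        complexes=(
            ComplexSpec("cx1", 8, ("A",), 0.1),
            ComplexSpec("cx2", 8, ("B",), 0.2),
        ),
        noise_sd=0.3,
        hitchhiker_sd=0.5,
        missing_rate=missing_rate,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """300 proteins, 2 planted complexes with disjoint cognate knockouts."""
    return simulate_dataset(small_sim_config())


@pytest.fixture(scope="session")
def small_profile(small_dataset):
    table, design, _ = small_dataset
    return impute_missing(compute_dependence(table, design))


@pytest.fixture(scope="session")
def small_truth(small_dataset):
    return small_dataset[2]
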