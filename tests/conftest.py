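import numpy as np
import pytest

from ghef.dataio import Dataset, SolubilityRecord, split_train_test
from ghef.synthdata import default_generator_config, generate_dataset


@pytest.fixture(scope="session")
def noisy_dataset() -> Dataset:
    """The standard 103-record synthetic fixture at 5% multiplicative noise."""
    return generate_dataset(default_generator_config(noise_cv=0.05, seed=42))


@pytest.fixture(scope="session")
def noiseless_dataset() -> Dataset:
    """The same design with noise switched off (targets on the exact surface)."""
    return generate_dataset(default_generator_config(noise_cv=0.0, seed=42))


@pytest.fixture(scope="session")
def train_test(noisy_dataset):
    return split_train_test(noisy_dataset, 0.2, seed=11)


def make_records(n: int, rng: np.random.Generator, compound: str = "X") -> list[SolubilityRecord]:
    """Random but physically valid records for property tests."""
    return [
        SolubilityRecord(
            temperature=float(rng.uniform(300, 350)),
            pressure=float(rng.uniform(10, 35)),
            molecular_weight=float(rng.uniform(200, 1000)),
            melting_point=float(rng.uniform(100, 250)),
            solubility=float(rng.uniform(0.01, 3.5)),
            compound=compound,
        )
        for _ in range(n)
    ]
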