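import numpy as np
import pytest

from twostep import (
    DescriptorTable,
    PeptideDataset,
    generate_descriptor_table,
    generate_regression_dataset,
)


@pytest.fixture(scope="session")
def small_table() -> DescriptorTable:
    """A deterministic 5-property descriptor table."""
    return generate_descriptor_table(5, seed=42)


@pytest.fixture(scope="session")
def table_643() -> DescriptorTable:
    """A 643-property synthetic table matching the literature table shape."""
    return generate_descriptor_table(643, seed=7)


@pytest.fixture()
def toy_dataset() -> PeptideDataset:
    return PeptideDataset(
        ids=["p1", "p2", "p3"],
        sequences=["ACDEF", "GHIKL", "MNPQR"],
        targets=np.array([6.0, 7.5, 5.5]),
    )


@pytest.fixture(scope="session")
def planted_problem(small_table):
    """A seeded planted-signal dataset shared by slow-ish tests."""
    dataset, truth = generate_regression_dataset(
        n=60, length=5, table=small_table, support_size=4,
        effect_size=1.0, noise_sd=0.1, seed=3,
    )
    return dataset, truth
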