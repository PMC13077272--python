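"""Shared fixtures: tiny synthetic cohorts and model configurations."""

from __future__ import annotations

import numpy as np
import pytest

from privsurv.privacy import AllocationConfig
from privsurv.survival import Dataset, ModelConfig, prepare_dataset
from privsurv.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """A fast cohort: 300 patients, small feature blocks."""
    return CohortSpec(
        n_patients=300,
        dims={"mRNA": 20, "miRNA": 12, "CNV": 15},
        n_informative={"mRNA": 3, "miRNA": 2, "CNV": 2},
        effect_size=1.0,
        censor_rate=0.3,
        missing_rate={"mRNA": 0.1, "miRNA": 0.1, "CNV": 0.1},
        n_categories={"cancer_type": 4, "gender": 2, "race": 3,
                      "histological_type": 3},
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cohort):
    blocks, records, _ = tiny_cohort
    return prepare_dataset(blocks, records)


def make_tiny_config(**overrides) -> ModelConfig:
    base = dict(
        hidden_widths={"mRNA": (12, 8), "miRNA": (10, 6), "CNV": (12, 8)},
        rep_length=8,
        heads=2,
        dropout_rate=0.1,
        head="cox",
        time_bins=6,
        epochs=5,
        batch_size=128,
        learning_rate=3e-3,
        weight_decay=1e-4,
        allocation=AllocationConfig(seed=0),
        seed=5,
    )
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture()
def tiny_config() -> ModelConfig:
    return make_tiny_config()


def random_dataset(rng: np.random.Generator, n: int = 40, d_cat: int = 4,
                   dims: dict | None = None) -> Dataset:
    """A structureless dataset for shape/determinism checks."""
    dims = dims or {"mRNA": 9, "miRNA": 7, "CNV": 8}
    return Dataset(
        cat=rng.integers(0, 2, size=(n, d_cat)),
        cont=rng.random((n, 1)),
        genomic={m: rng.random((n, p)) for m, p in dims.items()},
        times=rng.uniform(10.0, 500.0, n),
        events=rng.integers(0, 2, n),
        patient_ids=[f"P{i}" for i in range(n)],
    )
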