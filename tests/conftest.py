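"""Shared fixtures.

The heavy fixture is a scaled-down end-to-end experiment: a synthetic
5-class dataset with 5 planted discriminative genes per class among 1000,
and a 50-run GA/KNN ensemble over one 75/25 stratified partition.  It is
session-scoped because several tests measure different properties of the
same experiment.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaknn import (
    GAConfig,
    SyntheticSpec,
    generate_dataset,
    run_ensemble,
    stratified_split,
)

PLANTED_SPEC = SyntheticSpec(
    n_classes=5,
    samples_per_class=(30,) * 5,
    n_genes=1000,
    informative_per_class=5,
    effect_size=2.0,
    noise_sd=1.0,
    seed=1,
)

SCALED_CONFIG = GAConfig(
    chromosome_length=10,
    population_size=50,
    max_generations=50,
)


@pytest.fixture(scope="session")
def planted_data():
    """Log2-transformed planted-signal dataset with its ground truth."""
    dataset, truth = generate_dataset(PLANTED_SPEC)
    return dataset.apply_floor_log2(), truth


@pytest.fixture(scope="session")
def planted_partition(planted_data):
    dataset, _ = planted_data
    return stratified_split(dataset.class_labels, 0.75, seed=11)


@pytest.fixture(scope="session")
def planted_ensemble(planted_data, planted_partition):
    """50 GA/KNN runs on the planted dataset over one fixed partition."""
    dataset, _ = planted_data
    return run_ensemble(
        dataset, planted_partition, SCALED_CONFIG, n_runs=50, base_seed=100
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small, fast planted dataset for plumbing-level ensemble tests."""
    spec = SyntheticSpec(
        n_classes=3,
        samples_per_class=(10, 12, 8),
        n_genes=120,
        informative_per_class=4,
        effect_size=3.0,
        noise_sd=1.0,
        gender_proportion_per_class=(0.5, 0.7, 0.3),
        flagged_fraction=0.2,
        seed=7,
    )
    dataset, truth = generate_dataset(spec)
    return dataset.apply_floor_log2(), truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
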