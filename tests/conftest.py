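"""Shared fixtures: case-study models and small synthetic datasets.

Expensive artifacts (trained fits) are session-scoped so several tests can
share one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

import kinetransfer as kt
from kinetransfer.embedding import embed
from kinetransfer.training import TrainingConfig, fit


@pytest.fixture(scope="session")
def source():
    return kt.source_model()


@pytest.fixture(scope="session")
def target():
    return kt.target_model()


@pytest.fixture(scope="session")
def low_prior():
    return kt.low_prior_model()


@pytest.fixture(scope="session")
def target_dataset(target):
    """Three noisy batches from the ground-truth target model."""
    return kt.generate_dataset(target, 3, seed=42)


@pytest.fixture(scope="session")
def noise_free_dense(target):
    """Noise-free target data on a fine 4 h grid (parameter recovery)."""
    return kt.generate_dataset(target, 3, interval=4.0, noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def source_skeleton(source):
    return embed(source, Dmax=3)


@pytest.fixture(scope="session")
def quick_config():
    """Short training schedule for unit tests (not the study defaults)."""
    return TrainingConfig(seed=1, epochs=180, refit_epochs=60)


@pytest.fixture(scope="session")
def trained_fit(source, target_dataset, quick_config):
    """One short hybrid fit of the 12-slot source skeleton, shared by the
    pruning/attribution tests."""
    skeleton = embed(source, Dmax=3)
    return fit(skeleton, target_dataset, quick_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
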