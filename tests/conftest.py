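"""Shared fixtures: small synthetic epoch sets and desk-scale models."""

from __future__ import annotations

import numpy as np
import pytest

from glcnet.core_data import EpochSet
from glcnet.graph import AdjacencySpec
from glcnet.model import ModelConfig, build_glcnet
from glcnet.synthetic import SynthConfig, generate_epochs


@pytest.fixture(scope="session")
def tiny_epochs() -> EpochSet:
    """8 trials, 4 channels, 0.6 s at 250 Hz."""
    return generate_epochs(SynthConfig(
        n_trials_per_class=4, n_classes=2, n_channels=4, duration_s=0.6,
        class_channels=[[0, 1], [2, 3]], seed=101))


@pytest.fixture(scope="session")
def separable4_epochs() -> EpochSet:
    """The 4-class, 32-channel, T=500 end-to-end fixture (seed 303)."""
    return generate_epochs(SynthConfig(seed=303))


@pytest.fixture(scope="session")
def null_epochs() -> EpochSet:
    """Class-free noise: modulation depth 0 (seed 404)."""
    return generate_epochs(SynthConfig(modulation_depth=0.0,
                                       n_trials_per_class=50, seed=404))


def random_adjacency(n: int, seed: int = 0) -> AdjacencySpec:
    rng = np.random.default_rng(seed)
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return AdjacencySpec(mode="custom", matrix=a)


@pytest.fixture
def tiny_model_config() -> ModelConfig:
    """Smallest config exercising every branch (C=4, T=40, 18 filters)."""
    return ModelConfig(
        n_channels=4, n_times=40, n_classes=3, avg_window=8,
        spatial_filters=18, gcn_dims=(6, 5), lstm_hidden=4,
        adjacency=random_adjacency(4, seed=9))


@pytest.fixture
def tiny_model(tiny_model_config):
    return build_glcnet(tiny_model_config, seed=3)
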