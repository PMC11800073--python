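"""Shared fixtures: simulated datasets and smoke-scale trained generators.

The heavier objects (the 64^3 paired dataset and the trained generators)
are session-scoped so the projection, training and image-domain tests share
one simulation.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from pcct.fixtures import make_fixture
from pcct.gan import (
    LossWeights,
    NetConfig,
    TrainState,
    ViT,
    extract_patch_pairs,
    split_train_val,
    train_wgan,
)

SMOKE_SEEDS = (3, 4, 5, 6)


def smoke_net_config(seed: int = 3) -> NetConfig:
    """Desk-scale network widths used for CPU smoke training."""
    return replace(
        NetConfig.compact(n_bins=9),
        generator_base=8, disc_initial=8, disc_widths=(8, 16, 32, 64),
        disc_dense=128, vit_dim=16, vit_depth=1, vit_heads=2, seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    return make_fixture("tiny", seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    return make_fixture("small", seed=7)


@pytest.fixture(scope="session")
def smoke_pairs(small_dataset):
    pairs = extract_patch_pairs(small_dataset.distorted, small_dataset.ideal, 2000, seed=11)
    return split_train_val(pairs, 0.95)


@pytest.fixture(scope="session")
def smoke_training_runs(smoke_pairs):
    """Train the residual WGAN-ViT for each smoke seed; returns
    [(seed, generator, history), ...]."""
    train_set, val_set = smoke_pairs
    runs = []
    for seed in SMOKE_SEEDS:
        config = smoke_net_config(seed)
        vit = ViT(config)
        state = TrainState(epochs=5, batch_size=64, critic_steps=2, seed=seed)
        generator, history = train_wgan(
            train_set, val_set, config, LossWeights(), state, vit=vit
        )
        runs.append((seed, generator, history))
    return runs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
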