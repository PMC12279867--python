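"""Shared fixtures.

The scaled GAN training run (4 classes, 80 samples/class, hidden size 128,
2000 epochs) is expensive, so it is computed once per session and shared by
the fidelity and augmentation tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from nirgan import GanConfig, SimulatorConfig, build_class_profiles, simulate_dataset, train

SCALED_CHECKPOINTS = (100, 250, 500, 1000, 2000)


@pytest.fixture(scope="session")
def default_sim_config() -> SimulatorConfig:
    return SimulatorConfig()


@pytest.fixture(scope="session")
def default_dataset(default_sim_config):
    return simulate_dataset(default_sim_config)


@pytest.fixture(scope="session")
def scaled_sim_config() -> SimulatorConfig:
    return dataclasses.replace(SimulatorConfig(), n_per_class=80)


@pytest.fixture(scope="session")
def scaled_dataset(scaled_sim_config):
    return simulate_dataset(scaled_sim_config)


@pytest.fixture(scope="session")
def scaled_gan_run(scaled_dataset):
    """One full scaled training run: (config, TrainResult)."""
    cfg = GanConfig(
        hidden_size=128, total_epochs=2000, checkpoint_epochs=SCALED_CHECKPOINTS, seed=0
    )
    return cfg, train(scaled_dataset, cfg)


@pytest.fixture(scope="session")
def scaled_profiles(scaled_sim_config):
    return {p.label: p.mean_spectrum for p in build_class_profiles(scaled_sim_config)}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_tiny_gan_config(**kw) -> GanConfig:
    base = dict(
        batch_size=8,
        noise_dim=5,
        n_features=12,
        hidden_size=16,
        total_epochs=3,
        checkpoint_epochs=(2, 3),
        seed=0,
    )
    base.update(kw)
    return GanConfig(**base)


def make_tiny_dataset(n_per_class=10, n_bands=12, seed=0):
    cfg = dataclasses.replace(SimulatorConfig(), n_bands=n_bands, n_per_class=n_per_class, seed=seed)
    return simulate_dataset(cfg)
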