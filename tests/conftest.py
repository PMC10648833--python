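"""Shared fixtures: a small synthetic world and a trained extractor.

The trained extractor is session-scoped — the staged curriculum runs once
and is reused by every test that needs a learned metric.
"""

from __future__ import annotations

import numpy as np
import pytest

import driftreid as dr
from driftreid.extractor import EmbeddingDataset, TrainConfig, staged_train

N_IDENTITIES = 5
FRAMES_PER_IDENTITY = 30
FRAME_SIZE = (32, 32)


@pytest.fixture(scope="session")
def population():
    return dr.generate_population(N_IDENTITIES, seed=1)


@pytest.fixture(scope="session")
def frame_bank(population):
    """Low-noise frames: 5 identities x 30 frames at age 0."""
    rng = np.random.default_rng(2)
    images, labels = [], []
    for genotype in population:
        for _ in range(FRAMES_PER_IDENTITY):
            images.append(
                dr.render_frame(genotype, 0.0, int(rng.integers(2**31)),
                                size=FRAME_SIZE, noise_sigma=0.02))
            labels.append(genotype.identity_id)
    return np.asarray(images), np.asarray(labels)


@pytest.fixture(scope="session")
def bank_split(frame_bank):
    _, labels = frame_bank
    return dr.stratified_split(labels, test_fraction=0.2, seed=3)


@pytest.fixture(scope="session")
def train_config():
    return TrainConfig(seed=5, max_epochs=10)


@pytest.fixture(scope="session")
def trained_extractor(frame_bank, bank_split, train_config):
    """Extractor after the full semi_hard -> hard -> hardest curriculum."""
    images, labels = frame_bank
    train_idx, _ = bank_split
    model = dr.ConvEmbedder(input_size=32, seed=5)
    model, histories = staged_train(
        model, EmbeddingDataset(images[train_idx], labels[train_idx]), train_config)
    model.stage_histories = histories
    return model


@pytest.fixture()
def cheap_embedder():
    """Seeded random-projection embedder for store-bookkeeping tests."""
    return dr.RandomProjectionEmbedder(input_size=16, seed=11)


def make_session(identity_id: str, n_frames: int = 3, tick: int = 0,
                 session_id: str | None = None, seed: int = 0,
                 size=(16, 16)) -> dr.SessionRecord:
    """A session of flat seeded-noise frames, for store bookkeeping tests."""
    rng = np.random.default_rng(seed)
    frames = [rng.random((*size, 3)) for _ in range(n_frames)]
    return dr.SessionRecord(session_id=session_id or f"s_{identity_id}_{tick}_{seed}",
                            identity_id=identity_id, frames=frames, tick=tick)
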