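"""Shared fixtures: small synthetic datasets and a trained toy GAN.

Everything is generated programmatically and seeded; session scope keeps
the expensive pieces (EEG synthesis, GAN training) to one run each.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from eegaug.features import extract_features
from eegaug.gan import CWGANConfig, ConditionalWGAN
from eegaug.io import binarize_ratings
from eegaug.simulate import SynthConfig, iter_participants


def features_and_labels(cfg: SynthConfig, segment_s: float):
    feats_parts, ratings_parts, latents_parts = [], [], []
    for rec, lat in iter_participants(cfg):
        feats_parts.append(extract_features(rec.data, fs=cfg.fs, segment_s=segment_s))
        ratings_parts.append(rec.ratings)
        latents_parts.append(lat)
    feats = pd.concat(feats_parts, ignore_index=True)
    ratings = np.vstack(ratings_parts)
    return feats, binarize_ratings(ratings), ratings, np.vstack(latents_parts)


@pytest.fixture(scope="session")
def tiny_cfg() -> SynthConfig:
    """3 participants x 12 trials of 13-s EEG: fast but structurally real."""
    return dataclasses.replace(
        SynthConfig(), n_participants=3, n_trials=12, duration_s=13.0, seed=7
    )


@pytest.fixture(scope="session")
def tiny_records(tiny_cfg):
    return [rec for rec, _ in iter_participants(tiny_cfg)]


@pytest.fixture(scope="session")
def small_features():
    """Features/labels from 4 default-geometry participants (160 trials)."""
    cfg = dataclasses.replace(SynthConfig(), n_participants=4, seed=3)
    feats, labels, ratings, latents = features_and_labels(cfg, segment_s=60.0)
    return feats, labels


@pytest.fixture(scope="session")
def toy_gauss():
    """The two-class 2-D Gaussian toy problem: 500 labeled points."""
    rng = np.random.default_rng(42)
    n = 500
    y = rng.integers(0, 2, n)
    means = np.array([[-1.0, -1.0], [1.0, 1.0]])
    X = means[y] * 0.5 + 0.25 * rng.standard_normal((n, 2))
    return X, y


@pytest.fixture(scope="session")
def toy_gan(toy_gauss):
    """Conditional WGAN trained on the toy problem with the stated budget
    (500 generator steps, batch 32, learning rate 2e-4)."""
    X, y = toy_gauss
    return ConditionalWGAN(CWGANConfig(seed=7)).fit(X, y)
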