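"""Shared fixtures.

The expensive fixtures (trained segmenter, the 3-seed weighting-ablation
study) are session-scoped so that training happens once and every test that
needs a trained model reuses it.
"""

import warnings

import numpy as np
import pytest

from maskcxr import (PhantomConfig, generate_phantom, split_phantom,
                     SegTrainConfig, train_segmenter)
from maskcxr.experiments import segmentation_study, weighting_ablation_study


@pytest.fixture(scope="session")
def small_phantoms():
    cfg = PhantomConfig(image_size=64, n_samples=60, n_classes=4, seed=3,
                        label_prior=0.5, distractor_rate=0.5)
    return cfg, generate_phantom(cfg)


@pytest.fixture(scope="session")
def trained_segmenter(small_phantoms):
    _, samples = small_phantoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        train, val, test = split_phantom(samples, 0.8, 0.1, seed=3)
        seg, log = train_segmenter(train, val, SegTrainConfig(
            epochs=16, base_width=8, depth=3, seed=3))
    return seg, log, (train, val, test)


@pytest.fixture(scope="session")
def seg_study():
    """Three-seed tiny-U-Net segmentation study on 50-phantom datasets."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return segmentation_study(base_seed=0, n_seeds=3)


@pytest.fixture(scope="session")
def ablation():
    """Three-seed feature-weighting ablation on distractor-rich phantoms;
    keeps the first seed's trained models for localization tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return weighting_ablation_study(base_seed=0, n_seeds=3, keep_models=True)
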