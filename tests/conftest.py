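"""Shared fixtures: small synthetic datasets and bags, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import milniche as mn
from milniche.synthetic import CellType


def small_synth_config(seed: int = 11, n_per_class: int = 4) -> mn.SyntheticConfig:
    """A reduced generator config for fast unit tests (not the study conditions)."""
    return mn.SyntheticConfig(
        n_samples_per_class=n_per_class,
        image_size=96,
        n_channels=4,
        cell_types=[
            CellType("A", (1.0, 0.05, 0.05, 0.3), radius=5.0, n_cells=6),
            CellType("B", (0.05, 1.0, 0.05, 0.05), radius=5.0, n_cells=6),
            CellType("C", (0.05, 0.05, 1.0, 0.3), radius=6.0, n_cells=6, lobed=True),
        ],
        n_pairs=3,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_dataset() -> mn.SyntheticDataset:
    return mn.generate(small_synth_config())


@pytest.fixture(scope="session")
def normalized_images(small_dataset):
    return {im.sample_id: mn.normalize_channels(im) for im in small_dataset.images}


@pytest.fixture(scope="session")
def small_bags(small_dataset, normalized_images):
    recs = {r.sample_id: r for r in small_dataset.records}
    extractor = mn.CropExtractor(n_segments=60, m_crops=20, crop_size=32)
    sids = sorted(normalized_images)
    return extractor.transform([normalized_images[s] for s in sids], [recs[s] for s in sids])


@pytest.fixture(scope="session")
def tiny_trained_model(small_bags):
    """A small MIL model trained briefly on the reduced dataset."""
    clf = mn.QuantileMILClassifier(
        n_channels=4, width=8, depth=2, embed_dim=16, instance_size=32,
        n_quantiles=32, epochs=6, lr=3e-3, seed=0,
    )
    clf.fit(small_bags)
    return clf


def make_crop(patch: np.ndarray, mask: np.ndarray, sample_id: str = "s",
              sp_id: int = 0) -> mn.Crop:
    h = patch.shape[0]
    return mn.Crop(sample_id=sample_id, sp_id=sp_id, patch=patch.astype(np.float32),
                   mask=mask.astype(bool), irregularity=0.5, origin=(0, 0),
                   window=(0, 0, h, h))
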