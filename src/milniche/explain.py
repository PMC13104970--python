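"""SHAP-based prioritisation of outcome-associated image regions.

A random forest is trained on crop embeddings (each crop inheriting its
sample's outcome label); tree-SHAP attributions over the embedding
dimensions are summed in absolute value into a per-crop importance score.
Scores are painted back onto superpixels as an image-resolution importance
map, the top-scoring crops are selected, and cell-type co-occurrence is
counted within the prioritised crop footprints.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize
from sklearn.ensemble import RandomForestClassifier

from .mil import CropEmbedding
from .superpixels import Crop, Superpixel
from .treeshap import TreeShapExplainer

logger = logging.getLogger(__name__)


@dataclass
class ImportanceScore:
    """Per-crop SHAP attributions and their absolute sum."""

    sample_id: str
    sp_id: int
    shap_values: np.ndarray  # (d,)
    importance: float  # = sum_j |shap_values_j|


@dataclass
class ImportanceMap:
    """H x W raster: each scored superpixel painted with its importance."""

    sample_id: str
    raster: np.ndarray


def fit_crop_classifier(
    embeddings: Sequence[CropEmbedding],
    labels: Sequence[int],
    seed: int = 0,
    n_estimators: int = 200,
    min_samples_leaf: int = 5,
) -> RandomForestClassifier:
    """Fit a random forest on crop embeddings with inherited sample labels.

    Leaves hold at least ``min_samples_leaf`` crops: with singleton leaves
    the forest memorises uninformative crops and SHAP spreads spurious
    attribution mass over all embedding dimensions.
    """
    if len(embeddings) != len(labels):
        raise ValueError("embeddings and labels must align")
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("crop labels must contain >= 2 classes")
    X = np.stack([e.vector for e in embeddings])
    clf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1,
        min_samples_leaf=min_samples_leaf, oob_score=False,
    )
    clf.fit(X, y)
    return clf


def shap_importance(
    classifier: RandomForestClassifier,
    embedding: CropEmbedding,
    explainer: TreeShapExplainer | None = None,
    class_index: int = 1,
) -> ImportanceScore:
    """SHAP attributions of one crop embedding and their absolute sum."""
    if explainer is None:
        explainer = TreeShapExplainer(classifier, class_index=class_index)
    phi = explainer.shap_values(embedding.vector[None])[0]
    return ImportanceScore(
        sample_id=embedding.sample_id,
        sp_id=embedding.sp_id,
        shap_values=phi,
        importance=float(np.abs(phi).sum()),
    )


def score_crops(
    classifier: RandomForestClassifier,
    embeddings: Sequence[CropEmbedding],
    class_index: int = 1,
) -> list[ImportanceScore]:
    """Vectorised :func:`shap_importance` over many embeddings."""
    explainer = TreeShapExplainer(classifier, class_index=class_index)
    X = np.stack([e.vector for e in embeddings])
    phis = explainer.shap_values(X)
    return [
        ImportanceScore(e.sample_id, e.sp_id, phi, float(np.abs(phi).sum()))
        for e, phi in zip(embeddings, phis)
    ]


class CropImportanceScorer:
    """Estimator wrapper: fit a crop-level forest, then SHAP-score embeddings.

    ``fit`` trains the random forest (``classifier_``); ``score`` returns
    :class:`ImportanceScore` objects for new embeddings.
    """

    def __init__(self, n_estimators: int = 200, class_index: int = 1,
                 min_samples_leaf: int = 5, seed: int = 0):
        self.n_estimators = n_estimators
        self.class_index = class_index
        self.min_samples_leaf = min_samples_leaf
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"n_estimators": self.n_estimators,
                "class_index": self.class_index,
                "min_samples_leaf": self.min_samples_leaf, "seed": self.seed}

    def set_params(self, **params) -> "CropImportanceScorer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, embeddings: Sequence[CropEmbedding], labels: Sequence[int]):
        self.classifier_ = fit_crop_classifier(
            embeddings, labels, seed=self.seed, n_estimators=self.n_estimators,
            min_samples_leaf=self.min_samples_leaf,
        )
        self.explainer_ = TreeShapExplainer(self.classifier_, class_index=self.class_index)
        return self

    def score(self, embeddings: Sequence[CropEmbedding]) -> list[ImportanceScore]:
        X = np.stack([e.vector for e in embeddings])
        phis = self.explainer_.shap_values(X)
        return [
            ImportanceScore(e.sample_id, e.sp_id, phi, float(np.abs(phi).sum()))
            for e, phi in zip(embeddings, phis)
        ]


def build_importance_map(
    image_shape: tuple[int, int],
    superpixels: Sequence[Superpixel],
    scores: Sequence[ImportanceScore],
    sample_id: str = "",
) -> ImportanceMap:
    """Paint each scored superpixel's importance over its pixels (others 0)."""
    by_id = {sp.sp_id: sp for sp in superpixels}
    raster = np.zeros(image_shape, dtype=np.float64)
    for s in scores:
        if s.sp_id not in by_id:
            raise ValueError(f"score refers to unknown superpixel {s.sp_id}")
        raster[by_id[s.sp_id].member_mask] = s.importance
    return ImportanceMap(sample_id=sample_id, raster=raster)


def top_crops(scores: Sequence[ImportanceScore], n: int = 20) -> list[ImportanceScore]:
    """The n highest-importance scores; ties broken by (sample_id, sp_id)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(scores, key=lambda s: (-s.importance, s.sample_id, s.sp_id))
    return ranked[:n]


def crop_source_mask(crop: Crop) -> tuple[np.ndarray, tuple[int, int]]:
    """Map a crop's resampled mask back to source-image coordinates.

    Returns the boolean mask over the crop's clipped source window together
    with the window's top-left (row, col).
    """
    r0, c0, r1, c1 = crop.window
    ph, pw = r1 - r0, c1 - c0
    side = max(ph, pw)
    back = resize(crop.mask.astype(float), (side, side), order=0, anti_aliasing=False) > 0.5
    return back[:ph, :pw], (r0, c0)


def cooccurrence_counts(
    crops: Sequence[Crop],
    type_maps: Mapping[str, np.ndarray],
    type_names: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Count per-crop co-occurrence of cell types within crop mask footprints.

    ``type_maps`` holds one integer raster per sample (0 = background).  For
    each crop the set of types present under its back-projected mask is
    computed; every unordered pair present together adds 1 to its cell, and
    the diagonal counts single-type presence.  The returned table is
    symmetric.
    """
    present_sets = []
    for crop in crops:
        if crop.sample_id not in type_maps:
            warnings.warn(f"no type map for sample {crop.sample_id}; skipped", stacklevel=2)
            continue
        tmap = type_maps[crop.sample_id]
        mask, (r0, c0) = crop_source_mask(crop)
        window = tmap[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]]
        types = set(np.unique(window[mask])) - {0}
        if types:
            present_sets.append(sorted(types))
    all_types = sorted({t for s in present_sets for t in s})
    labels = [type_names.get(t, str(t)) if type_names else str(t) for t in all_types]
    idx = {t: i for i, t in enumerate(all_types)}
    counts = np.zeros((len(all_types), len(all_types)), dtype=int)
    for types in present_sets:
        for a in types:
            counts[idx[a], idx[a]] += 1
            for b in types:
                if b > a:
                    counts[idx[a], idx[b]] += 1
                    counts[idx[b], idx[a]] += 1
    return pd.DataFrame(counts, index=labels, columns=labels)
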