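"""Per-sample featurisations from crop embeddings.

Two sample representations feed the downstream outcome classifier:
mean-pooled embeddings of the SHAP-prioritised crops (MI features, length d)
and cluster-membership frequencies from a global k-means over crop
embeddings (frequency features, length K_clusters).  Crop embeddings can
also be clustered into prototypical microenvironment patterns, and samples
stratified into high/low abundance groups per pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .mil import CropEmbedding


@dataclass
class SampleFeaturization:
    sample_id: str
    kind: str  # "mi_pooled" | "frequency"
    vector: np.ndarray


@dataclass
class MicroenvironmentClustering:
    """k-means partition of crop embeddings into prototypical patterns."""

    k: int
    assignments: dict[tuple[str, int], int]  # (sample_id, sp_id) -> cluster
    centroids: np.ndarray
    seed: int


def mi_features(
    sample_id: str, prioritized: Sequence[CropEmbedding]
) -> SampleFeaturization:
    """Element-wise mean of the prioritised crop embeddings of one sample."""
    if len(prioritized) == 0:
        raise ValueError(f"no prioritised embeddings for sample {sample_id}")
    vec = np.mean([e.vector for e in prioritized], axis=0)
    return SampleFeaturization(sample_id=sample_id, kind="mi_pooled", vector=vec)


def _fit_kmeans(X: np.ndarray, k: int, seed: int) -> KMeans:
    if len(X) < k:
        raise ValueError(f"{len(X)} embeddings for k={k} clusters")
    if len(np.unique(X, axis=0)) < k:
        raise ValueError(f"fewer than k={k} distinct embedding points")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(X)
    return km


def frequency_features(
    all_embeddings: Sequence[CropEmbedding],
    n_clusters: int = 30,
    seed: int = 0,
) -> tuple[list[SampleFeaturization], MicroenvironmentClustering]:
    """Global k-means over embeddings, then per-sample cluster fractions.

    Each sample's vector entry j is the fraction of its crops assigned to
    cluster j; vectors are probability vectors (non-negative, summing to 1).
    """
    X = np.stack([e.vector for e in all_embeddings])
    km = _fit_kmeans(X, n_clusters, seed)
    labels = km.labels_
    clustering = MicroenvironmentClustering(
        k=n_clusters,
        assignments={(e.sample_id, e.sp_id): int(c) for e, c in zip(all_embeddings, labels)},
        centroids=km.cluster_centers_,
        seed=seed,
    )
    sample_ids = sorted({e.sample_id for e in all_embeddings})
    feats = []
    for sid in sample_ids:
        mine = labels[[i for i, e in enumerate(all_embeddings) if e.sample_id == sid]]
        vec = np.bincount(mine, minlength=n_clusters).astype(np.float64)
        feats.append(
            SampleFeaturization(sample_id=sid, kind="frequency", vector=vec / vec.sum())
        )
    return feats, clustering


def cluster_microenvironments(
    embeddings: Sequence[CropEmbedding], k: int = 10, seed: int = 0
) -> MicroenvironmentClustering:
    """Cluster (top-)crop embeddings into k prototypical microenvironments."""
    X = np.stack([e.vector for e in embeddings])
    km = _fit_kmeans(X, k, seed)
    return MicroenvironmentClustering(
        k=k,
        assignments={(e.sample_id, e.sp_id): int(c) for e, c in zip(embeddings, km.labels_)},
        centroids=km.cluster_centers_,
        seed=seed,
    )


def abundance_stratify(
    cluster_frequencies: Mapping[str, float], top_fraction: float = 0.25
) -> dict[str, bool]:
    """Label samples high (True) when their frequency is in the top fraction.

    The high group holds the ceil(top_fraction * n) samples with the largest
    frequencies; boundary ties are resolved by descending frequency then
    ascending sample id (with a warning).
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0, 1)")
    n = len(cluster_frequencies)
    if n < 4:
        raise ValueError("need >= 4 samples to stratify")
    n_high = int(np.ceil(top_fraction * n))
    ranked = sorted(cluster_frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
    boundary = ranked[n_high - 1][1]
    if any(v == boundary for _, v in ranked[n_high:]):
        warnings.warn(
            "ties at the abundance boundary resolved by sample id order", stacklevel=2
        )
    return {sid: i < n_high for i, (sid, _) in enumerate(ranked)}


class FrequencyFeaturizer:
    """sklearn-style transformer for cluster-frequency sample features.

    ``fit`` learns the global k-means on crop embeddings; ``transform``
    assigns embeddings to the learned clusters and returns per-sample
    frequency vectors.
    """

    def __init__(self, n_clusters: int = 30, seed: int = 0):
        self.n_clusters = n_clusters
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"n_clusters": self.n_clusters, "seed": self.seed}

    def set_params(self, **params) -> "FrequencyFeaturizer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, embeddings: Sequence[CropEmbedding], y=None) -> "FrequencyFeaturizer":
        X = np.stack([e.vector for e in embeddings])
        self.kmeans_ = _fit_kmeans(X, self.n_clusters, self.seed)
        return self

    def transform(self, embeddings: Sequence[CropEmbedding]) -> list[SampleFeaturization]:
        X = np.stack([e.vector for e in embeddings])
        labels = self.kmeans_.predict(X)
        sample_ids = sorted({e.sample_id for e in embeddings})
        out = []
        for sid in sample_ids:
            mine = labels[[i for i, e in enumerate(embeddings) if e.sample_id == sid]]
            vec = np.bincount(mine, minlength=self.n_clusters).astype(np.float64)
            out.append(SampleFeaturization(sid, "frequency", vec / vec.sum()))
        return out

    def fit_transform(self, embeddings: Sequence[CropEmbedding], y=None):
        return self.fit(embeddings).transform(embeddings)
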