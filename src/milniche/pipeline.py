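"""End-to-end orchestration: simulate/load -> crop -> train -> embed -> explain
-> featurize -> evaluate.

``run_pipeline`` drives the whole analysis in memory from a single
:class:`RunConfig`; the CLI wraps it with file I/O.  Samples are split once
(donor-grouped, label-stratified) into a representation-learning set used to
train the instance scorer and a held-out evaluation set on which embeddings,
SHAP scores, featurisations and the repeated-fold outcome AUROC are
computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .evaluate import EvaluationResult, repeated_fold_eval
from .explain import (
    CropImportanceScorer,
    ImportanceMap,
    ImportanceScore,
    build_importance_map,
    top_crops,
)
from .featurize import SampleFeaturization, frequency_features, mi_features
from .io import MultiplexImage, SampleRecord, normalize_channels
from .mil import CropEmbedding, QuantileMILClassifier
from .superpixels import CropExtractor, InstanceBag, partition_superpixels

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline hyperparameters with their defaults.

    The crop-selection and featurisation defaults (100 superpixels, 30 crops,
    top 20 SHAP crops, 30 frequency clusters, 10 microenvironment clusters,
    200 folds) are the method's standard settings; the network size is
    configurable and the toy preset (``toy_run_config``) uses a smaller
    network that trains on CPU in minutes.
    """

    # crop selection
    n_segments: int = 100
    m_crops: int = 30
    margin: int | None = None
    crop_size: int = 64
    compactness: float = 0.1
    # normalisation
    cofactor: float = 5.0
    clip_q: float = 99.0
    # model
    width: int = 32
    depth: int = 4
    embed_dim: int = 64
    n_quantiles: int = 8
    epochs: int = 20
    lr: float = 1e-3
    # explanation / featurisation
    top_n: int = 20
    n_freq_clusters: int = 30
    n_micro_clusters: int = 10
    rf_trees: int = 200
    # evaluation
    n_folds: int = 200
    test_fraction: float = 0.3
    mil_train_fraction: float = 0.5
    feature_kind: str = "mi_pooled"  # or "frequency"
    seed: int = 0


def toy_run_config(seed: int = 0, n_folds: int = 50) -> RunConfig:
    """Desk-scale settings: a small network on 32 x 32 crops.

    Q is raised to 128 so the upper quantile ranks resolve the few-percent
    fraction of informative tissue in the toy images.
    """
    return RunConfig(
        crop_size=32, width=24, depth=3, embed_dim=32, n_quantiles=128,
        epochs=40, lr=3e-3, n_folds=n_folds, seed=seed,
    )


@dataclass
class PipelineResult:
    config: RunConfig
    train_ids: list[str]
    eval_ids: list[str]
    bags: dict[str, InstanceBag]
    model: QuantileMILClassifier
    embeddings: list[CropEmbedding]  # evaluation-set crop embeddings
    scores: list[ImportanceScore]
    importance_maps: dict[str, ImportanceMap]
    mi_feats: list[SampleFeaturization]
    freq_feats: list[SampleFeaturization]
    evaluation: EvaluationResult
    loss_history: list[float] = field(default_factory=list)


def split_train_eval(
    records: Sequence[SampleRecord], fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """One donor-grouped, label-stratified split into (train, eval) sample ids."""
    rng = np.random.default_rng(seed)
    donor_label: dict[str, int] = {}
    by_donor: dict[str, list[str]] = {}
    for r in records:
        donor_label[r.donor_id] = r.label
        by_donor.setdefault(r.donor_id, []).append(r.sample_id)
    train, ev = [], []
    for k in sorted(set(donor_label.values())):
        donors = sorted(d for d, lab in donor_label.items() if lab == k)
        donors = list(rng.permutation(donors))
        n_train = max(1, int(round(fraction * len(donors))))
        for d in donors[:n_train]:
            train.extend(by_donor[d])
        for d in donors[n_train:]:
            ev.extend(by_donor[d])
    return sorted(train), sorted(ev)


def run_pipeline(
    images: Sequence[MultiplexImage],
    records: Sequence[SampleRecord],
    config: RunConfig | None = None,
    normalize: bool = True,
) -> PipelineResult:
    """Run the full analysis on in-memory images and manifest records."""
    cfg = config or RunConfig()
    rec_by_id = {r.sample_id: r for r in records}
    if normalize:
        images = [normalize_channels(im, cfg.cofactor, cfg.clip_q) for im in images]
    img_by_id = {im.sample_id: im for im in images}

    logger.info("extracting %d crops per image", cfg.m_crops)
    extractor = CropExtractor(
        n_segments=cfg.n_segments, m_crops=cfg.m_crops, margin=cfg.margin,
        crop_size=cfg.crop_size, compactness=cfg.compactness,
    )
    ordered = sorted(rec_by_id)
    bag_list = extractor.transform([img_by_id[s] for s in ordered],
                                   [rec_by_id[s] for s in ordered])
    bags = {b.sample_id: b for b in bag_list}

    train_ids, eval_ids = split_train_eval(records, cfg.mil_train_fraction, cfg.seed)
    n_channels = images[0].n_channels
    n_classes = len({r.label for r in records})

    logger.info("training MIL model on %d bags", len(train_ids))
    model = QuantileMILClassifier(
        n_channels=n_channels, n_classes=n_classes, width=cfg.width,
        depth=cfg.depth, embed_dim=cfg.embed_dim, instance_size=cfg.crop_size,
        n_quantiles=cfg.n_quantiles, epochs=cfg.epochs, lr=cfg.lr, seed=cfg.seed,
    )
    model.fit([bags[s] for s in train_ids])

    logger.info("embedding %d evaluation bags", len(eval_ids))
    embeddings = model.embed_crops([bags[s] for s in eval_ids])
    crop_labels = [rec_by_id[e.sample_id].label for e in embeddings]

    logger.info("SHAP scoring")
    scorer = CropImportanceScorer(n_estimators=cfg.rf_trees, seed=cfg.seed)
    scorer.fit(embeddings, crop_labels)
    scores = scorer.score(embeddings)

    # maps show the prioritised regions: the per-image top-n SHAP crops
    importance_maps = {}
    for sid in eval_ids:
        sps = partition_superpixels(img_by_id[sid], cfg.n_segments, cfg.compactness)
        mine = top_crops([s for s in scores if s.sample_id == sid], cfg.top_n)
        importance_maps[sid] = build_importance_map(
            img_by_id[sid].pixels.shape[:2], sps, mine, sample_id=sid
        )

    emb_by_key = {(e.sample_id, e.sp_id): e for e in embeddings}
    mi_feats = []
    for sid in eval_ids:
        mine = [s for s in scores if s.sample_id == sid]
        top = top_crops(mine, cfg.top_n)
        mi_feats.append(
            mi_features(sid, [emb_by_key[(s.sample_id, s.sp_id)] for s in top])
        )
    freq_feats, _clustering = frequency_features(
        embeddings, n_clusters=min(cfg.n_freq_clusters, max(2, len(embeddings) - 1)),
        seed=cfg.seed,
    )

    feats = mi_feats if cfg.feature_kind == "mi_pooled" else freq_feats
    evaluation = repeated_fold_eval(
        feats, [rec_by_id[s] for s in eval_ids], n_folds=cfg.n_folds,
        test_fraction=cfg.test_fraction, seed=cfg.seed, n_estimators=cfg.rf_trees,
    )
    return PipelineResult(
        config=cfg, train_ids=train_ids, eval_ids=eval_ids, bags=bags,
        model=model, embeddings=embeddings, scores=scores,
        importance_maps=importance_maps, mi_feats=mi_feats,
        freq_feats=freq_feats, evaluation=evaluation,
        loss_history=list(model.loss_history_),
    )
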