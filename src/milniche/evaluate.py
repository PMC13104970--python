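"""Downstream outcome prediction over repeated random folds.

Sample featurisations are scored with a random-forest classifier across many
random train/test splits that are grouped by donor (samples of one donor
never straddle a split) and stratified by outcome label at the donor level.
Test-sample positive-class probabilities are recorded per fold; the headline
number is the mean and standard deviation of per-fold AUROCs, alongside the
AUROC of fold-averaged per-sample probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .featurize import SampleFeaturization
from .io import SampleRecord

logger = logging.getLogger(__name__)


@dataclass
class EvaluationResult:
    mean_auroc: float
    std_auroc: float
    n_folds: int
    per_sample_mean_prob: dict[str, float]
    pooled_auroc: float  # AUROC of fold-averaged per-sample probabilities
    seed: int
    fold_aurocs: np.ndarray = field(repr=False, default=None)
    # per fold: (train sample ids, test sample ids), for split audits
    fold_assignments: list[tuple[list[str], list[str]]] = field(
        repr=False, default_factory=list
    )


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability that a random positive outscores a random negative (ties 1/2)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _donor_table(records: Sequence[SampleRecord]) -> tuple[list[str], dict[str, int]]:
    """Unique donors and each donor's label (must be consistent within donor)."""
    donor_label: dict[str, int] = {}
    for r in records:
        if r.donor_id in donor_label and donor_label[r.donor_id] != r.label:
            raise ValueError(f"donor {r.donor_id} carries conflicting labels")
        donor_label[r.donor_id] = r.label
    return sorted(donor_label), donor_label


def repeated_fold_eval(
    features: Sequence[SampleFeaturization],
    records: Sequence[SampleRecord],
    n_folds: int = 200,
    test_fraction: float = 0.3,
    seed: int = 0,
    n_estimators: int = 200,
    permute_labels: bool = False,
) -> EvaluationResult:
    """Repeated donor-grouped, label-stratified random-split evaluation.

    With ``permute_labels`` a fresh donor-level label permutation is drawn
    for every fold, giving the permutation-null distribution of the AUROC
    (its mean is ~0.5 when features carry no outcome information).
    """
    feats = {f.sample_id: f for f in features}
    records = [r for r in records if r.sample_id in feats]
    if len(records) < 6:
        raise ValueError("need >= 6 samples")
    labels = {r.sample_id: r.label for r in records}
    if len(set(labels.values())) < 2:
        raise ValueError("need >= 2 classes")
    donors, donor_label = _donor_table(records)
    by_donor: dict[str, list[str]] = {}
    for r in records:
        by_donor.setdefault(r.donor_id, []).append(r.sample_id)
    per_class_donors = {
        k: [d for d in donors if donor_label[d] == k] for k in set(donor_label.values())
    }
    X = {sid: feats[sid].vector for sid in labels}
    rng = np.random.default_rng(seed)
    fold_aurocs = []
    fold_assignments: list[tuple[list[str], list[str]]] = []
    prob_sum: dict[str, float] = {sid: 0.0 for sid in labels}
    prob_cnt: dict[str, int] = {sid: 0 for sid in labels}
    for fold in range(n_folds):
        if permute_labels:
            permuted = dict(zip(donors, rng.permutation([donor_label[d] for d in donors])))
            fold_labels = {r.sample_id: permuted[r.donor_id] for r in records}
            fold_class_donors = {
                k: [d for d in donors if permuted[d] == k] for k in set(permuted.values())
            }
        else:
            fold_labels = labels
            fold_class_donors = per_class_donors
        for attempt in range(100):
            test_donors: list[str] = []
            for k, dlist in fold_class_donors.items():
                n_test = max(1, int(round(test_fraction * len(dlist))))
                test_donors.extend(rng.choice(dlist, size=n_test, replace=False))
            test_ids = [s for d in test_donors for s in by_donor[d]]
            train_ids = [r.sample_id for r in records if r.sample_id not in set(test_ids)]
            train_labels = {fold_labels[s] for s in train_ids}
            test_labels = {fold_labels[s] for s in test_ids}
            if len(train_labels) >= 2 and len(test_labels) >= 2:
                break
            logger.info("fold %d redraw (attempt %d): class missing", fold, attempt)
        else:
            raise RuntimeError("could not draw a valid fold in 100 attempts")
        clf = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        clf.fit(np.stack([X[s] for s in train_ids]), [fold_labels[s] for s in train_ids])
        pos = list(clf.classes_).index(max(clf.classes_))
        probs = clf.predict_proba(np.stack([X[s] for s in test_ids]))[:, pos]
        fold_aurocs.append(auroc(probs, [fold_labels[s] for s in test_ids]))
        fold_assignments.append((sorted(train_ids), sorted(test_ids)))
        for s, p in zip(test_ids, probs):
            prob_sum[s] += p
            prob_cnt[s] += 1
    fold_aurocs = np.asarray(fold_aurocs)
    mean_prob = {
        s: prob_sum[s] / prob_cnt[s] for s in labels if prob_cnt[s] > 0
    }
    seen = [s for s in labels if s in mean_prob]
    pooled = auroc([mean_prob[s] for s in seen], [labels[s] for s in seen])
    return EvaluationResult(
        mean_auroc=float(fold_aurocs.mean()),
        std_auroc=float(fold_aurocs.std()),
        n_folds=n_folds,
        per_sample_mean_prob=mean_prob,
        pooled_auroc=pooled,
        seed=seed,
        fold_aurocs=fold_aurocs,
        fold_assignments=fold_assignments,
    )
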