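"""Multiple-instance learning with quantile-based aggregation.

A fully convolutional network scores every location of every selected crop
with per-class probabilities.  For each class the mask-filtered location
probabilities of the whole bag are pooled, sorted, and summarised by Q order
statistics picked at evenly spaced ranks: the q-th quantile of a sorted
vector of length n is its element at 1-based index ceil(n * (q - 0.5) / Q).
The K per-class quantile vectors are concatenated and passed through a
softmax to give the sample-level class probabilities, trained end-to-end
with categorical cross-entropy.  Gradients flow through the selected
order-statistic values only (the rank selection itself is hard).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .nn import Adam, InstanceFCN, softmax_lastaxis
from .superpixels import Crop, InstanceBag

logger = logging.getLogger(__name__)

PROB_CLAMP = 1e-12


@dataclass
class ProbabilityMap:
    """Per-location class probabilities of one crop with a validity raster."""

    probs: np.ndarray  # (h', h', K); rows sum to 1
    valid: np.ndarray  # (h', h') bool, aligned with the crop mask


@dataclass
class QuantileVector:
    """Q order statistics of pooled instance probabilities, per class."""

    per_class: np.ndarray  # (K, Q), non-decreasing along axis 1
    n_quantiles: int

    @property
    def concatenated(self) -> np.ndarray:
        return self.per_class.reshape(-1)


@dataclass
class SamplePrediction:
    class_probs: np.ndarray  # (K,), sums to 1

    @property
    def predicted_class(self) -> int:
        return int(np.argmax(self.class_probs))


@dataclass
class CropEmbedding:
    """Penultimate-layer representation of one crop, averaged over its mask."""

    sample_id: str
    sp_id: int
    vector: np.ndarray  # (d,)


# ---------------------------------------------------------------------------
# quantile aggregation primitives
# ---------------------------------------------------------------------------

def quantile_index(n: int, q: int, n_quantiles: int) -> int:
    """1-based index of the q-th of Q quantiles in a sorted length-n vector.

    ``ceil(n * (q - 0.5) / Q)``, computed in exact integer arithmetic.
    Non-decreasing in q and always within 1..n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 1 <= q <= n_quantiles:
        raise ValueError(f"q={q} outside 1..{n_quantiles}")
    idx = -((-n * (2 * q - 1)) // (2 * n_quantiles))
    return int(min(max(idx, 1), n))


def quantile_aggregate(values: np.ndarray, n_quantiles: int) -> np.ndarray:
    """Pick the Q rank-spaced order statistics from an ascending value list."""
    values = np.asarray(values)
    n = len(values)
    if n == 0:
        raise ValueError("cannot aggregate an empty value list")
    idx = np.array([quantile_index(n, q, n_quantiles) - 1 for q in range(1, n_quantiles + 1)])
    return values[idx]


def mask_filter(pmap: ProbabilityMap, class_k: int) -> np.ndarray:
    """Class-k probabilities at mask-valid locations, sorted ascending.

    Falls back to all locations (logged) when the validity raster is empty.
    """
    valid = pmap.valid
    if not valid.any():
        logger.warning("empty validity raster; falling back to all locations")
        valid = np.ones_like(pmap.valid, dtype=bool)
    vals = pmap.probs[valid, class_k]
    return np.sort(vals, kind="stable")


def cross_entropy(predictions: list[SamplePrediction], labels) -> float:
    """Mean negative log-probability of the true class (clamped at 1e-12)."""
    labels = np.asarray(labels, dtype=int)
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must align")
    total = 0.0
    for pred, y in zip(predictions, labels):
        p = float(pred.class_probs[y])
        if p < PROB_CLAMP:
            logger.warning("true-class probability %.3g clamped", p)
            p = PROB_CLAMP
        total -= math.log(p)
    return total / len(predictions)


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class QuantileMILClassifier:
    """FCN instance scorer + quantile aggregation, trained with cross-entropy.

    sklearn-style estimator over :class:`InstanceBag` inputs.  ``fit`` trains
    the network (Adam, one bag per step); fitted state lives in ``model_``
    and ``loss_history_``.  ``embed_crops`` exposes the penultimate-layer
    crop embeddings used downstream for explanation and featurisation.

    Parameters
    ----------
    n_channels, n_classes
        Input marker planes N and outcome classes K.
    width, depth, embed_dim, instance_size
        FCN feature width, number of 3x3 conv layers, embedding dimension d,
        and expected crop size h.
    n_quantiles
        Q, the number of rank-spaced order statistics per class.
    epochs, lr, seed
        Training schedule; the seed fixes initialisation and bag order.
    """

    def __init__(
        self,
        n_channels: int,
        n_classes: int = 2,
        width: int = 32,
        depth: int = 4,
        embed_dim: int = 64,
        instance_size: int = 64,
        n_quantiles: int = 8,
        epochs: int = 20,
        lr: float = 1e-3,
        readout_lr_scale: float = 0.1,
        seed: int = 0,
    ):
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if n_quantiles < 1:
            raise ValueError("n_quantiles must be >= 1")
        if embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")
        self.n_channels = n_channels
        self.n_classes = n_classes
        self.width = width
        self.depth = depth
        self.embed_dim = embed_dim
        self.instance_size = instance_size
        self.n_quantiles = n_quantiles
        self.epochs = epochs
        self.lr = lr
        self.readout_lr_scale = readout_lr_scale
        self.seed = seed

    # -- sklearn plumbing ----------------------------------------------------
    _param_names = (
        "n_channels", "n_classes", "width", "depth", "embed_dim",
        "instance_size", "n_quantiles", "epochs", "lr", "readout_lr_scale", "seed",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "QuantileMILClassifier":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- core forward pieces ---------------------------------------------------
    def _check_crop(self, crop: Crop) -> None:
        h = self.instance_size
        if crop.patch.shape != (h, h, self.n_channels):
            raise ValueError(
                f"crop shape {crop.patch.shape} incompatible with model "
                f"(h={h}, N={self.n_channels})"
            )

    def forward_instance(self, crop: Crop) -> ProbabilityMap:
        """Per-location class probabilities for one crop (inference mode)."""
        self._check_model()
        self._check_crop(crop)
        probs, _ = self.model_.forward(crop.patch)
        return ProbabilityMap(probs=probs, valid=crop.mask.astype(bool))

    def predict_sample(self, bag: InstanceBag) -> tuple[SamplePrediction, QuantileVector]:
        """Bag-level prediction: pooled, mask-filtered quantile aggregation."""
        self._check_model()
        if len(bag) == 0:
            raise ValueError("empty bag")
        pmaps = [self.forward_instance(c) for c in bag.crops]
        return self._aggregate([p.probs for p in pmaps], [p.valid for p in pmaps])

    def _aggregate(self, probs_list, valid_list) -> tuple[SamplePrediction, QuantileVector]:
        K, Q = self.n_classes, self.n_quantiles
        if not any(v.any() for v in valid_list):
            valid_list = [np.ones_like(v, dtype=bool) for v in valid_list]
            logger.warning("all masks empty in bag; using all locations")
        per_class = np.empty((K, Q), dtype=np.float64)
        for k in range(K):
            pooled = np.concatenate(
                [p[v, k] for p, v in zip(probs_list, valid_list) if v.any()]
            )
            per_class[k] = quantile_aggregate(np.sort(pooled, kind="stable"), Q)
        qv = QuantileVector(per_class=per_class, n_quantiles=Q)
        logits = qv.concatenated @ self.readout_weight_ + self.readout_bias_
        s = softmax_lastaxis(logits.reshape(1, -1))
        return SamplePrediction(class_probs=s.ravel()), qv

    def _init_readout(self) -> tuple[np.ndarray, np.ndarray]:
        # initialised at the block-sum pattern: class logit = sum of that
        # class's quantile values, refined during training
        K, Q = self.n_classes, self.n_quantiles
        w = np.zeros((K * Q, K), dtype=np.float32)
        for k in range(K):
            w[k * Q : (k + 1) * Q, k] = 1.0
        return w, np.zeros(K, dtype=np.float32)

    # -- training --------------------------------------------------------------
    def fit(self, bags: list[InstanceBag], y=None) -> "QuantileMILClassifier":
        """Train on labelled bags; records per-epoch mean loss in ``loss_history_``."""
        labels = np.array([b.label for b in bags], dtype=int) if y is None else np.asarray(y, int)
        if len(bags) == 0:
            raise ValueError("no bags")
        if len(np.unique(labels)) < 2:
            raise ValueError("training requires >= 2 distinct classes")
        if labels.max() >= self.n_classes:
            raise ValueError("label outside 0..K-1")
        self.model_ = InstanceFCN(
            self.n_channels, self.n_classes, width=self.width,
            depth=self.depth, embed_dim=self.embed_dim, seed=self.seed,
        )
        self.readout_weight_, self.readout_bias_ = self._init_readout()
        fcn_params = self.model_.parameters()
        # the readout has few parameters and a direct gradient path; slow it
        # down so the loss is driven into the convolutional features
        self._opt = Adam(
            fcn_params + [self.readout_weight_, self.readout_bias_],
            lr=self.lr,
            lr_scales=[1.0] * len(fcn_params) + [self.readout_lr_scale] * 2,
        )
        rng = np.random.default_rng(self.seed + 1)
        self.loss_history_ = []
        for _epoch in range(self.epochs):
            order = rng.permutation(len(bags))
            losses = [self._train_step(bags[i], int(labels[i])) for i in order]
            self.loss_history_.append(float(np.mean(losses)))
        self.classes_ = np.arange(self.n_classes)
        return self

    def _train_step(self, bag: InstanceBag, label: int) -> float:
        loss, grads = self._loss_and_grads(bag, label)
        self._opt.step(grads)
        return loss

    def _loss_and_grads(self, bag: InstanceBag, label: int):
        """Cross-entropy of one bag and gradients for all trainable arrays.

        Gradients are returned in optimiser order: the FCN parameter list
        followed by the readout weight and bias.
        """
        K, Q = self.n_classes, self.n_quantiles
        h = self.instance_size
        # 1) cheap forward over the whole bag
        probs_list, valid_list = [], []
        for crop in bag.crops:
            self._check_crop(crop)
            probs, _ = self.model_.forward(crop.patch)
            probs_list.append(probs)
            valid_list.append(crop.mask.astype(bool))
        if not any(v.any() for v in valid_list):
            valid_list = [np.ones_like(v, dtype=bool) for v in valid_list]
        # 2) pooled sort per class with provenance of every selected element
        V = np.empty(K * Q, dtype=np.float64)
        picks: list[tuple[int, int, int, int]] = []  # (vec_pos, crop_idx, row, col)
        for k in range(K):
            vals, crops_ix, rows, cols = [], [], [], []
            for m, (p, v) in enumerate(zip(probs_list, valid_list)):
                if not v.any():
                    continue
                r, c = np.nonzero(v)
                vals.append(p[r, c, k])
                crops_ix.append(np.full(len(r), m))
                rows.append(r)
                cols.append(c)
            vals = np.concatenate(vals)
            crops_ix = np.concatenate(crops_ix)
            rows = np.concatenate(rows)
            cols = np.concatenate(cols)
            order = np.argsort(vals, kind="stable")
            n = len(vals)
            for q in range(1, Q + 1):
                j = order[quantile_index(n, q, Q) - 1]
                pos = k * Q + (q - 1)
                V[pos] = vals[j]
                picks.append((pos, int(crops_ix[j]), int(rows[j]), int(cols[j])))
        # 3) sample-level readout softmax and its gradient
        logits = V @ self.readout_weight_ + self.readout_bias_
        s = softmax_lastaxis(logits.reshape(1, -1)).ravel()
        loss = -math.log(max(float(s[label]), PROB_CLAMP))
        dlogits = s.copy()
        dlogits[label] -= 1.0
        dW = np.outer(V, dlogits)
        db = dlogits
        dV = self.readout_weight_ @ dlogits
        # 4) route gradients to the selected probability entries per crop
        dprobs: dict[int, np.ndarray] = {}
        for pos, m, r, c in picks:
            g = dprobs.setdefault(m, np.zeros((h, h, K), dtype=np.float32))
            g[r, c, pos // Q] += dV[pos]
        # 5) backprop through the FCN for touched crops only
        grads = [np.zeros_like(p) for p in self.model_.parameters()]
        for m, g in dprobs.items():
            _, _, cache = self.model_.forward_cached(bag.crops[m].patch)
            for acc, gi in zip(grads, self.model_.backward(cache, g)):
                acc += gi
        return loss, grads + [dW, db]

    # -- inference -------------------------------------------------------------
    def _check_model(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("model is not fitted; call fit() or init_model() first")

    def init_model(self) -> "QuantileMILClassifier":
        """Initialise network weights without training (e.g. for probing)."""
        self.model_ = InstanceFCN(
            self.n_channels, self.n_classes, width=self.width,
            depth=self.depth, embed_dim=self.embed_dim, seed=self.seed,
        )
        self.readout_weight_, self.readout_bias_ = self._init_readout()
        self.loss_history_ = []
        self.classes_ = np.arange(self.n_classes)
        return self

    def predict_proba(self, bags: list[InstanceBag]) -> np.ndarray:
        return np.stack([self.predict_sample(b)[0].class_probs for b in bags])

    def predict(self, bags: list[InstanceBag]) -> np.ndarray:
        return self.predict_proba(bags).argmax(axis=1)

    def embed_crop(self, crop: Crop) -> CropEmbedding:
        """Mask-averaged penultimate feature map of one crop (d values)."""
        self._check_model()
        self._check_crop(crop)
        _, feat = self.model_.forward(crop.patch)
        mask = crop.mask.astype(bool)
        if not mask.any():
            logger.warning("empty mask for crop %s/%d; averaging all locations",
                           crop.sample_id, crop.sp_id)
            mask = np.ones_like(mask, dtype=bool)
        vec = feat[mask].mean(axis=0).astype(np.float64)
        return CropEmbedding(sample_id=crop.sample_id, sp_id=crop.sp_id, vector=vec)

    def embed_crops(self, bags: list[InstanceBag]) -> list[CropEmbedding]:
        return [self.embed_crop(c) for b in bags for c in b.crops]
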