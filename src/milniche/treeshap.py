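"""Exact SHAP values for tree ensembles (path-dependent algorithm).

Implements the polynomial-time tree-SHAP recursion: a decision path is
maintained with, per unique feature on the path, the fraction of one-paths
(feature known, following the explained point) and zero-paths (feature
unknown, split by training-cover proportions), together with permutation
weights that are extended at every split and unwound at the leaves.  Leaf
contributions yield per-feature Shapley values of the cover-weighted
conditional expectation of the tree output.  The heavy recursion is
numba-compiled; inputs are the node arrays of fitted sklearn trees.

Local accuracy holds exactly: sum(phi) + expected_value equals the model
output for the explained point.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from sklearn.ensemble import RandomForestClassifier


@njit(cache=False)
def _extend(fi, zf, of, pw, depth, pzf, pof, pfi):
    fi[depth] = pfi
    zf[depth] = pzf
    of[depth] = pof
    pw[depth] = 1.0 if depth == 0 else 0.0
    for i in range(depth - 1, -1, -1):
        pw[i + 1] += pof * pw[i] * (i + 1.0) / (depth + 1.0)
        pw[i] = pzf * pw[i] * (depth - i) / (depth + 1.0)


@njit(cache=False)
def _unwind(fi, zf, of, pw, depth, path_index):
    one_f = of[path_index]
    zero_f = zf[path_index]
    nxt = pw[depth]
    for i in range(depth - 1, -1, -1):
        if one_f != 0.0:
            tmp = pw[i]
            pw[i] = nxt * (depth + 1.0) / ((i + 1.0) * one_f)
            nxt = tmp - pw[i] * zero_f * (depth - i) / (depth + 1.0)
        else:
            pw[i] = pw[i] * (depth + 1.0) / (zero_f * (depth - i))
    for i in range(path_index, depth):
        fi[i] = fi[i + 1]
        zf[i] = zf[i + 1]
        of[i] = of[i + 1]


@njit(cache=False)
def _unwound_sum(zf, of, pw, depth, path_index):
    one_f = of[path_index]
    zero_f = zf[path_index]
    nxt = pw[depth]
    total = 0.0
    for i in range(depth - 1, -1, -1):
        if one_f != 0.0:
            tmp = nxt * (depth + 1.0) / ((i + 1.0) * one_f)
            total += tmp
            nxt = pw[i] - tmp * zero_f * (depth - i) / (depth + 1.0)
        else:
            total += pw[i] / zero_f * (depth + 1.0) / (depth - i)
    return total


@njit(cache=False)
def _recurse(left, right, feature, threshold, value, weight, x, phi,
             node, depth, fi, zf, of, pw, pzf, pof, pfi):
    fi = fi.copy()
    zf = zf.copy()
    of = of.copy()
    pw = pw.copy()
    _extend(fi, zf, of, pw, depth, pzf, pof, pfi)
    if left[node] < 0:  # leaf
        for i in range(1, depth + 1):
            w = _unwound_sum(zf, of, pw, depth, i)
            phi[fi[i]] += w * (of[i] - zf[i]) * value[node]
    else:
        split = feature[node]
        if x[split] <= threshold[node]:
            hot, cold = left[node], right[node]
        else:
            hot, cold = right[node], left[node]
        inc_zero = 1.0
        inc_one = 1.0
        path_index = 0
        found = False
        for j in range(depth + 1):
            if fi[j] == split:
                path_index = j
                found = True
                break
        if found:
            inc_zero = zf[path_index]
            inc_one = of[path_index]
            _unwind(fi, zf, of, pw, depth, path_index)
            depth -= 1
        hot_frac = weight[hot] / weight[node]
        cold_frac = weight[cold] / weight[node]
        _recurse(left, right, feature, threshold, value, weight, x, phi,
                 hot, depth + 1, fi, zf, of, pw, inc_zero * hot_frac, inc_one, split)
        _recurse(left, right, feature, threshold, value, weight, x, phi,
                 cold, depth + 1, fi, zf, of, pw, inc_zero * cold_frac, 0.0, split)


@njit(cache=False)
def _tree_shap_single(left, right, feature, threshold, value, weight, x, phi, max_depth):
    fi = np.full(max_depth + 2, -1, dtype=np.int64)
    zf = np.zeros(max_depth + 2, dtype=np.float64)
    of = np.zeros(max_depth + 2, dtype=np.float64)
    pw = np.zeros(max_depth + 2, dtype=np.float64)
    _recurse(left, right, feature, threshold, value, weight, x, phi,
             0, 0, fi, zf, of, pw, 1.0, 1.0, -1)


def _tree_arrays(tree, class_index: int):
    """Node arrays of one fitted sklearn tree with scalar leaf outputs."""
    t = tree.tree_
    value = np.asarray(t.value, dtype=np.float64)  # (n_nodes, 1, n_out)
    v = value[:, 0, :]
    if v.shape[1] > 1:
        row_sums = v.sum(axis=1, keepdims=True)
        row_sums[row_sums == 0] = 1.0
        out = (v / row_sums)[:, class_index]
    else:
        out = v[:, 0]
    return (
        t.children_left.astype(np.int64),
        t.children_right.astype(np.int64),
        t.feature.astype(np.int64),
        t.threshold.astype(np.float64),
        np.ascontiguousarray(out),
        t.weighted_n_node_samples.astype(np.float64),
        int(t.max_depth),
    )


def tree_expected_value(tree, class_index: int = 1) -> float:
    """Cover-weighted mean leaf output of one tree (the SHAP base value)."""
    left, right, _, _, value, weight, _ = _tree_arrays(tree, class_index)
    leaves = left < 0
    return float((value[leaves] * weight[leaves]).sum() / weight[0])


def tree_shap_values(tree, X: np.ndarray, class_index: int = 1) -> np.ndarray:
    """Per-feature SHAP values of a single fitted tree for each row of X."""
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    left, right, feature, threshold, value, weight, max_depth = _tree_arrays(
        tree, class_index
    )
    phi = np.zeros((X.shape[0], X.shape[1]), dtype=np.float64)
    for r in range(X.shape[0]):
        _tree_shap_single(left, right, feature, threshold, value, weight,
                          X[r], phi[r], max_depth)
    return phi


class TreeShapExplainer:
    """SHAP attributions for a fitted random-forest classifier.

    Explains the predicted probability of ``class_index`` (default: the
    positive class).  ``shap_values(X)`` returns an (n, d) array whose row
    sums plus :attr:`expected_value` equal ``predict_proba(X)[:, class_index]``
    to floating-point accuracy.
    """

    def __init__(self, model: RandomForestClassifier, class_index: int = 1):
        if not hasattr(model, "estimators_"):
            raise ValueError("model must be a fitted tree ensemble")
        self.model = model
        self.class_index = class_index
        self.expected_value = float(
            np.mean([tree_expected_value(t, class_index) for t in model.estimators_])
        )

    def shap_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.model.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.model.n_features_in_}"
            )
        phi = np.zeros((X.shape[0], X.shape[1]), dtype=np.float64)
        for t in self.model.estimators_:
            phi += tree_shap_values(t, X, self.class_index)
        return phi / len(self.model.estimators_)
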