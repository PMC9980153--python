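"""Exact Shapley attributions for scikit-learn tree ensembles.

Implements the polynomial-time path-dependent TreeSHAP recursion: for each
decision tree, feature coalitions are weighted by the fraction of training
cover flowing down each branch, and the Shapley value of every feature on a
root-to-leaf path is accumulated from an incrementally maintained path
polynomial (the EXTEND / UNWIND scheme). Cost is O(leaves * depth^2) per
sample per tree, against exponential subset enumeration.

The attributions satisfy local accuracy exactly:

    sum_j phi_j(x) + E[f(X)] = f(x)

where the expectation is over the tree's training cover distribution and
f(x) is the probability of the positive class for random forests, or the
decision margin (log-odds) for gradient-boosted trees.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor


class UnsupportedModelError(TypeError):
    """Shapley attribution requested for a model that is not a supported tree ensemble."""


class _Tree:
    """Flat view of one fitted sklearn tree with scalar leaf outputs."""

    __slots__ = ("left", "right", "feature", "threshold", "value", "weight")

    def __init__(self, sk_tree, classifier: bool):
        t = sk_tree.tree_
        self.left = t.children_left
        self.right = t.children_right
        self.feature = t.feature
        self.threshold = t.threshold
        v = t.value[:, 0, :]
        if classifier:
            # per-node positive-class fraction (robust to sklearn storing
            # counts or normalized frequencies)
            self.value = v[:, 1] / v.sum(axis=1)
        else:
            self.value = v[:, 0].astype(float)
        self.weight = t.weighted_n_node_samples

    def expected_value(self) -> float:
        leaves = self.left == -1
        return float((self.value[leaves] * self.weight[leaves]).sum() / self.weight[0])


def _unwound_sum(po, pz, pw, d, i):
    one, zero = po[i], pz[i]
    total = 0.0
    if one != 0.0:
        nxt = pw[d]
        for j in range(d - 1, -1, -1):
            tmp = nxt / ((j + 1) * one)
            total += tmp
            nxt = pw[j] - tmp * zero * (d - j)
    else:
        for j in range(d - 1, -1, -1):
            total += pw[j] / (zero * (d - j))
    return total * (d + 1)


def _unwind(pf, pz, po, pw, d, i):
    one, zero = po[i], pz[i]
    nxt = pw[d]
    for j in range(d - 1, -1, -1):
        if one != 0.0:
            tmp = pw[j]
            pw[j] = nxt * (d + 1) / ((j + 1) * one)
            nxt = tmp - pw[j] * zero * (d - j) / (d + 1)
        else:
            pw[j] = pw[j] * (d + 1) / (zero * (d - j))
    for j in range(i, d):
        pf[j] = pf[j + 1]
        pz[j] = pz[j + 1]
        po[j] = po[j + 1]
    pf.pop(), pz.pop(), po.pop(), pw.pop()


def _recurse(tree, node, x, phi, pf, pz, po, pw, pzf, pof, pfi):
    # extend the path with the incoming split (fresh copies: siblings and
    # ancestors keep their own state)
    pf = pf + [pfi]
    pz = pz + [pzf]
    po = po + [pof]
    pw = pw + [1.0 if not pw else 0.0]
    d = len(pw) - 1
    for i in range(d - 1, -1, -1):
        pw[i + 1] += pof * pw[i] * (i + 1) / (d + 1)
        pw[i] = pzf * pw[i] * (d - i) / (d + 1)

    if tree.left[node] == -1:  # leaf
        val = tree.value[node]
        for i in range(1, d + 1):
            w = _unwound_sum(po, pz, pw, d, i)
            phi[pf[i]] += w * (po[i] - pz[i]) * val
        return

    f = int(tree.feature[node])
    left, right = int(tree.left[node]), int(tree.right[node])
    hot, cold = (left, right) if x[f] <= tree.threshold[node] else (right, left)
    wn = tree.weight[node]
    hot_zf = tree.weight[hot] / wn
    cold_zf = tree.weight[cold] / wn
    izf = iof = 1.0
    for i in range(1, d + 1):  # previously split on this feature?
        if pf[i] == f:
            izf, iof = pz[i], po[i]
            _unwind(pf, pz, po, pw, d, i)
            d -= 1
            break
    _recurse(tree, hot, x, phi, pf, pz, po, pw, hot_zf * izf, iof, f)
    _recurse(tree, cold, x, phi, pf, pz, po, pw, cold_zf * izf, 0.0, f)


def _single_tree_shap(tree: _Tree, x: np.ndarray, n_features: int) -> np.ndarray:
    phi = np.zeros(n_features)
    _recurse(tree, 0, x, phi, [], [], [], [], 1.0, 1.0, -1)
    return phi


def _decompose(model):
    """Return (list of _Tree, scale, offset) so that the model output equals
    offset + scale * sum(tree outputs)."""
    if isinstance(model, RandomForestClassifier):
        trees = [_Tree(e, classifier=True) for e in model.estimators_]
        return trees, 1.0 / len(trees), 0.0
    if isinstance(model, GradientBoostingClassifier):
        if model.estimators_.shape[1] != 1:
            raise UnsupportedModelError("only binary gradient boosting is supported")
        trees = [_Tree(e, classifier=False) for e in model.estimators_[:, 0]]
        init = float(model._raw_predict_init(np.zeros((1, model.n_features_in_)))[0, 0])
        return trees, model.learning_rate, init
    if isinstance(model, (DecisionTreeClassifier, DecisionTreeRegressor)):
        return [_Tree(model, classifier=isinstance(model, DecisionTreeClassifier))], 1.0, 0.0
    raise UnsupportedModelError(
        f"{type(model).__name__} is not a supported tree model (RF, GBT or single tree)"
    )


def shap_values(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-sample, per-feature Shapley attributions for a tree model.

    Returns ``(phi, expected_value)`` with ``phi`` of shape
    ``(n_samples, n_features)``. For every sample,
    ``phi[i].sum() + expected_value`` equals the model output: the positive
    class probability (random forest / classification tree) or the decision
    margin (gradient boosting).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    trees, scale, offset = _decompose(model)
    n, p = X.shape
    phi = np.zeros((n, p))
    for tree in trees:
        for i in range(n):
            phi[i] += _single_tree_shap(tree, X[i], p)
    phi *= scale
    expected = offset + scale * sum(t.expected_value() for t in trees)
    return phi, float(expected)
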