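"""Independent brute-force reference implementations used as test oracles.

Everything here is written as directly as possible from the defining
formulas — explicit window counting, pairwise enumeration, subset
enumeration — and deliberately shares no code with the package.
"""

from itertools import combinations, product
from math import factorial, sqrt

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Descriptor oracles
# ---------------------------------------------------------------------------

def brute_tpc(seq):
    counts = {"".join(t): 0 for t in product(AA, repeat=3)}
    for i in range(len(seq) - 2):
        counts[seq[i : i + 3]] += 1
    total = len(seq) - 2
    return np.array([counts["".join(t)] / total for t in product(AA, repeat=3)])


def brute_grouped_tripeptide(seq, groups):
    """groups: ordered list of residue strings."""
    of = {aa: gi for gi, g in enumerate(groups) for aa in g}
    n = len(groups)
    counts = np.zeros(n**3)
    for i in range(len(seq) - 2):
        a, b, c = of[seq[i]], of[seq[i + 1]], of[seq[i + 2]]
        counts[a * n * n + b * n + c] += 1
    return counts / (len(seq) - 2)


def brute_geary(seq, scale, nlag):
    """Direct double-loop Geary coefficients for one z-standardized scale."""
    vals = np.array([scale[a] for a in AA])
    z = {a: (scale[a] - vals.mean()) / vals.std() for a in AA}
    p = [z[a] for a in seq]
    L = len(p)
    pbar = sum(p) / L
    denom = sum((x - pbar) ** 2 for x in p)
    out = []
    for d in range(1, nlag + 1):
        if denom == 0:
            out.append(0.0)
            continue
        num = sum((p[i] - p[i + d]) ** 2 for i in range(L - d))
        out.append((L - 1) / (2 * (L - d)) * num / denom)
    return np.array(out)


def brute_ctdd(seq, attributes):
    """attributes: dict name -> (class1, class2, class3) residue strings."""
    L = len(seq)
    out = []
    for groups in attributes.values():
        for g in groups:
            pos = [i + 1 for i, a in enumerate(seq) if a in set(g)]
            if not pos:
                out.extend([0.0] * 5)
                continue
            n = len(pos)
            picks = [pos[0]]
            for q in (0.25, 0.5, 0.75, 1.0):
                k = int(np.ceil(n * q))
                picks.append(pos[k - 1])
            out.extend(x / L * 100.0 for x in picks)
    return np.array(out)


def brute_qsorder(seq, dm, aa_index, lag, w):
    L = len(seq)
    f = [seq.count(a) for a in AA]
    tau = []
    for d in range(1, lag + 1):
        tau.append(
            sum(dm[aa_index[seq[i]], aa_index[seq[i + d]]] ** 2 for i in range(L - d))
        )
    denom = sum(f) + w * sum(tau)
    return np.array([x / denom for x in f] + [w * t / denom for t in tau])


# ---------------------------------------------------------------------------
# Metric oracles
# ---------------------------------------------------------------------------

def brute_roc_auc(scores, labels):
    """Mann-Whitney concordance: P(s+ > s-) + 0.5 P(s+ = s-)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_average_precision(scores, labels):
    """AP = sum_k (R_k - R_{k-1}) P_k over distinct score thresholds, descending."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        precision = tp / int(pred.sum())
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def brute_sensitivity_at_fpr(scores, labels, cap):
    """Exhaustive threshold sweep (positive iff score >= t)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    best = 0.0
    for t in list(scores) + [scores.max() + 1]:
        pred = scores >= t
        fp = int((pred & (labels == 0)).sum())
        tp = int((pred & (labels == 1)).sum())
        if fp / (labels == 0).sum() <= cap:
            best = max(best, tp / (labels == 1).sum())
    return best


# ---------------------------------------------------------------------------
# Shapley oracle: exact subset enumeration over one tree's features
# ---------------------------------------------------------------------------

def _tree_cond_exp(tree, x, S):
    """Expected tree output with features in S fixed to x, others marginalized
    over the training cover of each split."""

    def rec(n):
        if tree.left[n] == -1:
            return tree.value[n]
        f = tree.feature[n]
        if f in S:
            child = tree.left[n] if x[f] <= tree.threshold[n] else tree.right[n]
            return rec(child)
        wl = tree.weight[tree.left[n]]
        wr = tree.weight[tree.right[n]]
        return (wl * rec(tree.left[n]) + wr * rec(tree.right[n])) / (wl + wr)

    return rec(0)


def brute_shap(trees, scale, x, n_features):
    """Exact Shapley values by enumerating all coalitions of each tree's
    split features. Exponential; only for small trees."""
    phi = np.zeros(n_features)
    for t in trees:
        feats = sorted(set(int(f) for f in t.feature if f >= 0))
        M = len(feats)
        for j in feats:
            others = [f for f in feats if f != j]
            for r in range(M):
                for S in combinations(others, r):
                    wgt = factorial(r) * factorial(M - r - 1) / factorial(M)
                    with_j = _tree_cond_exp(t, x, set(S) | {j})
                    without = _tree_cond_exp(t, x, set(S))
                    phi[j] += wgt * (with_j - without)
    return phi * scale


def brute_difference_score(ref, mut, indices):
    return sqrt(sum((ref[i] - mut[i]) ** 2 for i in indices))
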