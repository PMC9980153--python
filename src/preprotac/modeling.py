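"""Tree-ensemble training, cross-validated evaluation and voting ensembles.

The modeling protocol: a 4-hyperparameter grid search (n_estimators,
max_depth, min_samples_split, min_samples_leaf) scored by 5-fold stratified
CV mean ROC-AUC; final evaluation and model building by repeated stratified
5-fold CV (2 repeats -> 10 fold models); a soft-voting ensemble averaging
the 10 fold-model probabilities with equal weight; and threshold calibration
on the averaged false-positive-rate-vs-threshold curve from the 10
validation splits.

Prediction convention everywhere: positive iff score >= threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn import metrics as skm
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold

from . import __version__
from .descriptors import FeatureMatrix

ALGORITHMS = ("rf", "gbt")

#: Candidate values for the four tuned hyperparameters.
DEFAULT_GRID: dict[str, list] = {
    "n_estimators": [100, 200, 500],
    "max_depth": [None, 5, 10, 20],
    "min_samples_split": [2, 5, 10],
    "min_samples_leaf": [1, 2, 4],
}

#: Shared threshold lattice on which per-fold FPR curves are averaged
#: (folds have different score supports; a fixed lattice makes the mean
#: well-defined).
THRESHOLD_LATTICE = np.round(np.linspace(0.0, 1.0, 101), 2)


class MetricUndefinedError(ValueError):
    """A metric was requested on degenerate labels (single class / no negatives)."""


class CalibrationError(ValueError):
    """No threshold on the lattice achieves the requested false positive rate."""


def _as_xy(features, labels) -> tuple[np.ndarray, np.ndarray]:
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} samples but {y.shape[0]} labels")
    return X, y


def _make_estimator(algorithm: str, hyperparameters: dict, seed: int):
    if algorithm == "rf":
        return RandomForestClassifier(random_state=seed, **hyperparameters)
    if algorithm == "gbt":
        return GradientBoostingClassifier(random_state=seed, **hyperparameters)
    raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {algorithm!r}")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """ROC-AUC; equals the Mann-Whitney concordance P(s+ > s-) + 0.5 P(tie)."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise MetricUndefinedError("ROC-AUC needs both classes present")
    return float(skm.roc_auc_score(y, np.asarray(scores, dtype=float)))


def pr_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Precision-recall curve and average precision.

    Returns ``(precision, recall, thresholds, average_precision)`` with
    AP = sum_k (R_k - R_{k-1}) P_k over score-ranked thresholds.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise MetricUndefinedError("PR curve needs both classes present")
    s = np.asarray(scores, dtype=float)
    precision, recall, thresholds = skm.precision_recall_curve(y, s)
    ap = float(skm.average_precision_score(y, s))
    return precision, recall, thresholds, ap


def fpr_at_threshold(scores, labels, threshold: float) -> float:
    """FP / (FP + TN) with prediction positive iff score >= threshold."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    neg = y == 0
    if not neg.any():
        raise MetricUndefinedError("FPR needs at least one negative sample")
    return float((s[neg] >= threshold).sum() / neg.sum())


def fpr_curve(scores, labels, thresholds=THRESHOLD_LATTICE) -> np.ndarray:
    return np.array([fpr_at_threshold(scores, labels, t) for t in thresholds])


def sensitivity_at_fpr(scores, labels, fpr_cap: float) -> float:
    """Maximum recall over thresholds whose FPR does not exceed ``fpr_cap``."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if not (y == 0).any() or not (y == 1).any():
        raise MetricUndefinedError("sensitivity-at-FPR needs both classes")
    n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
    best = 0.0
    # candidate thresholds: each observed score and one above the maximum
    for t in np.concatenate([np.unique(s), [s.max() + 1.0]]):
        pred = s >= t
        fpr = (pred & (y == 0)).sum() / n_neg
        if fpr <= fpr_cap:
            best = max(best, (pred & (y == 1)).sum() / n_pos)
    return float(best)


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

@dataclass
class FoldModel:
    """One fitted tree-ensemble classifier with its training provenance."""

    algorithm: str
    hyperparameters: dict
    estimator: object
    train_ids: list[str]
    seed: int

    def predict_proba(self, features) -> np.ndarray:
        X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
        return self.estimator.predict_proba(X)[:, 1]


@dataclass
class EnsembleModel:
    """Voting ensemble over fitted fold models.

    ``soft`` mode scores a sample as the unweighted mean of member
    probabilities; ``consensus`` mode predicts positive only when every
    member clears its own threshold.
    """

    members: list[FoldModel]
    mode: str = "soft"
    threshold: float = 0.90
    member_thresholds: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("an ensemble needs at least 2 members")
        if self.mode not in ("soft", "consensus"):
            raise ValueError(f"mode must be 'soft' or 'consensus', got {self.mode!r}")

    def predict_proba(self, features) -> np.ndarray:
        return soft_vote(self.members, features)

    def predict(self, features) -> np.ndarray:
        if self.mode == "consensus":
            thr = self.member_thresholds or [self.threshold] * len(self.members)
            return consensus_vote(self.members, features, thr)
        return (self.predict_proba(features) >= self.threshold).astype(int)


def soft_vote(members, features) -> np.ndarray:
    """Unweighted mean of member positive-class probabilities."""
    probs = [m.predict_proba(features) for m in members]
    return np.mean(probs, axis=0)


def consensus_vote(members, features, member_thresholds) -> np.ndarray:
    """Positive iff every member scores at or above its own threshold."""
    if len(member_thresholds) != len(members):
        raise ValueError("one threshold per member required")
    votes = [
        m.predict_proba(features) >= t for m, t in zip(members, member_thresholds)
    ]
    return np.logical_and.reduce(votes).astype(int)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Per-fold and aggregate metrics from repeated stratified CV."""

    scheme: dict
    folds: list[dict] = field(default_factory=list)

    @property
    def mean_roc_auc(self) -> float:
        return float(np.mean([f["roc_auc"] for f in self.folds]))

    @property
    def sd_roc_auc(self) -> float:
        return float(np.std([f["roc_auc"] for f in self.folds]))

    @property
    def mean_average_precision(self) -> float:
        return float(np.mean([f["average_precision"] for f in self.folds]))

    def mean_fpr_curve(self) -> np.ndarray:
        """Average of the per-fold FPR-vs-threshold curves on the shared lattice."""
        return np.mean([f["fpr_curve"] for f in self.folds], axis=0)

    def summary(self) -> dict:
        return {
            "scheme": self.scheme,
            "n_folds": len(self.folds),
            "mean_roc_auc": self.mean_roc_auc,
            "sd_roc_auc": self.sd_roc_auc,
            "mean_average_precision": self.mean_average_precision,
            "sd_average_precision": float(np.std([f["average_precision"] for f in self.folds])),
        }

    def to_jsonable(self) -> dict:
        out = self.summary()
        out["threshold_lattice"] = THRESHOLD_LATTICE.tolist()
        out["mean_fpr_curve"] = self.mean_fpr_curve().tolist()
        out["folds"] = [
            {
                "roc_auc": f["roc_auc"],
                "average_precision": f["average_precision"],
                "roc_curve": {"fpr": f["roc_curve"][0].tolist(), "tpr": f["roc_curve"][1].tolist()},
                "pr_curve": {
                    "precision": f["pr_curve"][0].tolist(),
                    "recall": f["pr_curve"][1].tolist(),
                },
                "fpr_curve": f["fpr_curve"].tolist(),
            }
            for f in self.folds
        ]
        return out


def _check_stratifiable(y: np.ndarray, n_splits: int) -> None:
    pos, neg = (y == 1).sum(), (y == 0).sum()
    if pos < n_splits or neg < n_splits:
        raise ValueError(
            f"stratified {n_splits}-fold CV needs >= {n_splits} samples per class "
            f"(got {pos} positive / {neg} negative)"
        )


def grid_search(
    features,
    labels,
    algorithm: str = "rf",
    grid: dict[str, list] | None = None,
    seed: int = 0,
    n_splits: int = 5,
) -> tuple[dict, list[dict]]:
    """Exhaustive hyperparameter search scored by stratified-CV mean ROC-AUC.

    Returns the best combination and the full per-combination results. Ties
    are broken by the first combination in deterministic enumeration order
    (the Cartesian product of the grid values in their listed order).
    """
    X, y = _as_xy(features, labels)
    _check_stratifiable(y, n_splits)
    grid = DEFAULT_GRID if grid is None else grid
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(cv.split(X, y))
    keys = list(grid)
    results = []
    best: dict | None = None
    for combo in itertools.product(*(grid[k] for k in keys)):
        hp = dict(zip(keys, combo))
        aucs = []
        for tr, te in splits:
            est = _make_estimator(algorithm, hp, seed)
            est.fit(X[tr], y[tr])
            aucs.append(roc_auc(est.predict_proba(X[te])[:, 1], y[te]))
        entry = {"hyperparameters": hp, "mean_roc_auc": float(np.mean(aucs))}
        results.append(entry)
        if best is None or entry["mean_roc_auc"] > best["mean_roc_auc"]:
            best = entry
    return dict(best["hyperparameters"]), results


def repeated_stratified_cv(
    features,
    labels,
    algorithm: str = "rf",
    hyperparameters: dict | None = None,
    n_splits: int = 5,
    n_repeats: int = 2,
    seed: int = 0,
) -> tuple[CVReport, list[FoldModel]]:
    """Repeated stratified K-fold CV; defaults give the 10 fold models
    (5 splits x 2 repeats) behind the final soft-voting ensemble.

    Each fold model is fitted on its training split and scored on the
    held-out split; the report collects ROC, PR and FPR-vs-threshold curves
    per fold. Fully deterministic in (seed, data).
    """
    X, y = _as_xy(features, labels)
    _check_stratifiable(y, n_splits)
    hyperparameters = hyperparameters or {}
    sample_ids = (
        features.sample_ids
        if isinstance(features, FeatureMatrix)
        else [str(i) for i in range(len(y))]
    )
    rskf = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=n_repeats, random_state=seed)
    report = CVReport(
        scheme={"n_splits": n_splits, "n_repeats": n_repeats, "seed": seed,
                "algorithm": algorithm, "hyperparameters": hyperparameters}
    )
    fold_models: list[FoldModel] = []
    for fold_idx, (tr, te) in enumerate(rskf.split(X, y)):
        fold_seed = (seed + 1000 * fold_idx + 1) % (2**31 - 1)
        est = _make_estimator(algorithm, hyperparameters, fold_seed)
        est.fit(X[tr], y[tr])
        fm = FoldModel(
            algorithm=algorithm,
            hyperparameters=dict(hyperparameters),
            estimator=est,
            train_ids=[sample_ids[i] for i in tr],
            seed=fold_seed,
        )
        fold_models.append(fm)
        s = fm.predict_proba(X[te])
        prec, rec, _, ap = pr_curve(s, y[te])
        fpr_pts, tpr_pts, _ = skm.roc_curve(y[te], s)
        report.folds.append(
            {
                "roc_auc": roc_auc(s, y[te]),
                "average_precision": ap,
                "roc_curve": (fpr_pts, tpr_pts),
                "pr_curve": (prec, rec),
                "fpr_curve": fpr_curve(s, y[te]),
            }
        )
    return report, fold_models


def calibrate_threshold(cv_report: CVReport, target_fpr: float) -> float:
    """Smallest lattice threshold whose mean validation FPR is <= target.

    The averaged FPR-vs-threshold curve is treated as piecewise constant on
    the lattice (no interpolation); an unreachable target raises.
    """
    mean_fpr = cv_report.mean_fpr_curve()
    ok = np.nonzero(mean_fpr <= target_fpr)[0]
    if ok.size == 0:
        raise CalibrationError(
            f"mean FPR {mean_fpr[-1]:.4f} at threshold 1.0 still exceeds target {target_fpr}"
        )
    return float(THRESHOLD_LATTICE[ok[0]])


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(model, path: str | Path) -> None:
    """Persist a FoldModel/EnsembleModel in a version-stamped container."""
    joblib.dump(
        {"format_version": _FORMAT_VERSION, "package_version": __version__, "model": model},
        path,
    )


def load_model(path: str | Path):
    payload = joblib.load(path)
    if not isinstance(payload, dict) or "model" not in payload:
        raise ValueError(f"{path}: not a recognised model container")
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported model format version {payload.get('format_version')}"
        )
    return payload["model"]
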