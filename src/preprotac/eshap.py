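"""eSHAP: embedding-SHAP key-residue analysis.

The trained classifier sees only embedding features, whose coordinates have
no direct biological meaning. eSHAP grounds them back onto the sequence in
three steps:

1. Rank embedding features by the magnitude of their Shapley attributions
   over the training samples and keep the top k (default 20).
2. Mutate every residue, one position at a time, to its opposite-property
   amino acid (charge flips, polar <-> hydrophobic).
3. Score each position by the Euclidean distance between the parent and
   mutant embeddings restricted to the selected features:

       difference_score(x) = sqrt( sum_{n=1..k} (f_n_ref - f_n_mut)^2 )

Positions whose perturbation moves the model-relevant embedding coordinates
the most are reported as key positions for degradability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import FeatureMatrix
from .embedding import Embedder
from .modeling import EnsembleModel, FoldModel
from .sequence_io import ProteinRecord, scan_mutants
from .treeshap import shap_values


@dataclass
class ShapSelection:
    """Top-k embedding features ranked by global Shapley importance."""

    feature_indices: list[int]
    importances: list[float]
    source_model: str
    k: int

    def __post_init__(self) -> None:
        if len(set(self.feature_indices)) != len(self.feature_indices):
            raise ValueError("feature indices must be unique")
        imp = np.asarray(self.importances)
        if (np.diff(imp) > 1e-12).any():
            raise ValueError("importances must be sorted non-increasing")


@dataclass
class MutScanResult:
    """Per-position difference scores for one protein."""

    protein_id: str
    position_scores: list[tuple[int, str, str, float]]  # (pos, ref, alt, score)
    ranked_positions: list[int]
    params: dict

    def to_frame(self) -> pd.DataFrame:
        rank_of = {p: r for r, p in enumerate(self.ranked_positions, start=1)}
        return pd.DataFrame(
            [
                {
                    "protein_id": self.protein_id,
                    "position": p,
                    "ref_aa": ref,
                    "alt_aa": alt,
                    "score": score,
                    "rank": rank_of[p],
                }
                for p, ref, alt, score in self.position_scores
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "protein_id": self.protein_id,
            "params": self.params,
            "positions": [
                {"position": p, "ref_aa": r, "alt_aa": a, "score": s}
                for p, r, a, s in self.position_scores
            ],
            "ranked_positions": self.ranked_positions,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _model_name(model) -> str:
    if isinstance(model, EnsembleModel):
        return f"ensemble({model.mode},n={len(model.members)})"
    if isinstance(model, FoldModel):
        return f"{model.algorithm}(seed={model.seed})"
    return type(model).__name__


def select_top_features(
    model,
    features: FeatureMatrix,
    k: int = 20,
    require_embedding: bool = True,
) -> ShapSelection:
    """Rank features by mean |Shapley attribution| over the given samples.

    ``model`` may be a FoldModel, a soft-voting EnsembleModel (attributions
    are the member mean, matching the linearity of the soft vote) or a bare
    sklearn tree model. Signed attributions cancel across samples, so global
    importance uses the mean magnitude; ties are broken by lower feature
    index. ``require_embedding`` enforces that the feature matrix came from
    an embedder, the intended input space of the difference score.
    """
    if require_embedding and not features.provenance.startswith("embedder:"):
        raise ValueError(
            f"eSHAP feature selection expects embedding features, got provenance "
            f"{features.provenance!r} (pass require_embedding=False to override)"
        )
    if not 1 <= k <= len(features.feature_names):
        raise ValueError(f"k must be in 1..{len(features.feature_names)}, got {k}")

    if isinstance(model, EnsembleModel):
        per_member = [shap_values(m.estimator, features.values)[0] for m in model.members]
        phi = np.mean(per_member, axis=0)
    elif isinstance(model, FoldModel):
        phi, _ = shap_values(model.estimator, features.values)
    else:
        phi, _ = shap_values(model, features.values)

    importance = np.abs(phi).mean(axis=0)
    order = np.lexsort((np.arange(len(importance)), -importance))[:k]
    return ShapSelection(
        feature_indices=[int(i) for i in order],
        importances=[float(importance[i]) for i in order],
        source_model=_model_name(model),
        k=k,
    )


def difference_score(
    ref_vec: np.ndarray, mut_vec: np.ndarray, selection: ShapSelection
) -> float:
    """Euclidean norm of (reference - mutant) restricted to the selected features."""
    ref = np.asarray(ref_vec, dtype=float)
    mut = np.asarray(mut_vec, dtype=float)
    if ref.shape != mut.shape:
        raise ValueError(f"vector shapes differ: {ref.shape} vs {mut.shape}")
    idx = np.asarray(selection.feature_indices)
    if idx.size and (idx.max() >= ref.size or idx.min() < 0):
        raise ValueError("selection indices out of range for the given vectors")
    d = ref[idx] - mut[idx]
    return float(np.sqrt((d * d).sum()))


def eshap_scan(
    record: ProteinRecord,
    embedder: Embedder,
    model,
    training_features: FeatureMatrix | None = None,
    k: int = 20,
    selection: ShapSelection | None = None,
) -> MutScanResult:
    """Full eSHAP mutational scan of one protein.

    Builds the opposite-property mutant set, embeds the parent and every
    mutant, and scores each position by the selected-feature embedding shift.
    The feature selection is either passed in (``selection``) or computed
    from ``training_features`` with :func:`select_top_features`. Ranking is
    by score descending, ties broken by lower position. Deterministic given
    (sequence, embedder, model, k).
    """
    if selection is None:
        if training_features is None:
            raise ValueError("provide either a ShapSelection or the training FeatureMatrix")
        selection = select_top_features(model, training_features, k)
    mutset = scan_mutants(record)
    ref_vec = embedder.embed(record.sequence)
    scores = []
    for m in mutset.mutants:
        mut_vec = embedder.embed(m.sequence)
        scores.append((m.position, m.ref_aa, m.alt_aa, difference_score(ref_vec, mut_vec, selection)))
    ranked = [p for p, _, _, s in sorted(scores, key=lambda t: (-t[3], t[0]))]
    return MutScanResult(
        protein_id=record.id,
        position_scores=scores,
        ranked_positions=ranked,
        params={"k": selection.k, "embedder": embedder.name, "model": selection.source_model},
    )


def report_key_positions(result: MutScanResult, top_n: int) -> pd.DataFrame:
    """Top-n key positions as a table sorted by score descending."""
    frame = result.to_frame().sort_values("rank").head(top_n).reset_index(drop=True)
    return frame
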