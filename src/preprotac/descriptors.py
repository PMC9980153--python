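"""Classical sequence descriptors for degradability classification.

Implements the six descriptor families that performed best among the
composition/order/property encodings evaluated for this task: tripeptide
composition (TPC), grouped tripeptide composition (GTPC), Geary
autocorrelation, the distribution part of composition-transition-distribution
(CTDD), conjoint triad (CTriad) and quasi-sequence-order (QSOrder).

All composition-style outputs are raw frequencies that sum to 1, which keeps
feature scales stable across sequence lengths.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from . import properties as P
from .sequence_io import LabeledDataset, ProteinRecord

logger = logging.getLogger(__name__)


class SequenceLengthError(ValueError):
    """Sequence too short for the requested descriptor/parameters."""


@dataclass
class FeatureMatrix:
    """Dense samples x features table with provenance.

    Invariants enforced on construction: finite values, unique feature names,
    shape consistent with the id/name lists.
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    provenance: str = "unknown"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.feature_names):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} ids / {len(self.feature_names)} names"
            )
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError(f"non-finite values in feature matrix ({self.provenance})")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def slice_columns(self, start: int, stop: int) -> "FeatureMatrix":
        return FeatureMatrix(
            sample_ids=list(self.sample_ids),
            feature_names=self.feature_names[start:stop],
            values=self.values[:, start:stop],
            provenance=self.provenance,
            params=dict(self.params),
        )


# ---------------------------------------------------------------------------
# Individual descriptor families
# ---------------------------------------------------------------------------

_TRIPEPTIDES = ["".join(t) for t in itertools.product(P.AMINO_ACIDS, repeat=3)]

def tpc(record: ProteinRecord) -> np.ndarray:
    """Tripeptide composition: frequency of each of the 20^3 ordered
    tripeptides over the L-2 windows; sums to 1."""
    seq = record.sequence
    if len(seq) < 3:
        raise SequenceLengthError(f"{record.id}: TPC needs length >= 3, got {len(seq)}")
    v = np.zeros(8000)
    for i in range(len(seq) - 2):
        a, b, c = (P.AA_INDEX[x] for x in seq[i : i + 3])
        v[(a * 20 + b) * 20 + c] += 1
    return v / (len(seq) - 2)


_GTPC_NAMES = list(P.GTPC_GROUPS)
_GTPC_OF = {aa: gi for gi, g in enumerate(_GTPC_NAMES) for aa in P.GTPC_GROUPS[g]}

def gtpc(record: ProteinRecord) -> np.ndarray:
    """Grouped tripeptide composition over the 5 physicochemical groups
    (aliphatic, aromatic, positive, negative, uncharged-polar); 125 dims."""
    seq = record.sequence
    if len(seq) < 3:
        raise SequenceLengthError(f"{record.id}: GTPC needs length >= 3, got {len(seq)}")
    v = np.zeros(125)
    for i in range(len(seq) - 2):
        a, b, c = (_GTPC_OF[x] for x in seq[i : i + 3])
        v[(a * 5 + b) * 5 + c] += 1
    return v / (len(seq) - 2)


def geary(
    record: ProteinRecord,
    scales: dict[str, dict[str, float]] | None = None,
    nlag: int = 8,
) -> np.ndarray:
    """Geary spatial autocorrelation of residue properties along the chain.

    For a z-standardized property scale p and lag d:

        C(d) = [(L-1) / (2(L-d))] * sum_i (p_i - p_{i+d})^2
                                  / sum_i (p_i - p_mean)^2

    Values near 1 indicate no autocorrelation, below 1 positive correlation.
    A constant-property sequence has a zero denominator; the coefficient is
    then reported as 0.0 (logged), keeping the matrix finite.
    """
    scales = P.GEARY_SCALES if scales is None else scales
    seq = record.sequence
    L = len(seq)
    if L <= nlag:
        raise SequenceLengthError(f"{record.id}: Geary needs length > nlag={nlag}, got {L}")
    out = np.empty(len(scales) * nlag)
    j = 0
    for name, scale in scales.items():
        vals = np.array([scale[aa] for aa in P.AMINO_ACIDS])
        z = {aa: (scale[aa] - vals.mean()) / vals.std() for aa in P.AMINO_ACIDS}
        p = np.array([z[aa] for aa in seq])
        denom = ((p - p.mean()) ** 2).sum()
        for d in range(1, nlag + 1):
            if denom == 0.0:
                logger.debug("%s: constant %s profile, Geary lag %d set to 0", record.id, name, d)
                out[j] = 0.0
            else:
                num = ((p[: L - d] - p[d:]) ** 2).sum()
                out[j] = (L - 1) / (2 * (L - d)) * num / denom
            j += 1
    return out


def ctdd(record: ProteinRecord) -> np.ndarray:
    """Distribution descriptor: for 7 physicochemical attributes x 3 classes,
    the sequence positions (as % of length) of the first, 25%, 50%, 75% and
    100% occurrences of the class. 105 values in [0, 100]; absent class -> 0s.
    """
    seq = record.sequence
    L = len(seq)
    out = np.zeros(7 * 3 * 5)
    j = 0
    for attr, groups in P.CTD_ATTRIBUTES.items():
        for g in groups:
            gset = set(g)
            pos = [i + 1 for i, aa in enumerate(seq) if aa in gset]
            if pos:
                n = len(pos)
                idxs = [0] + [int(np.ceil(n * q)) - 1 for q in (0.25, 0.5, 0.75, 1.0)]
                for k in idxs:
                    out[j] = pos[k] / L * 100.0
                    j += 1
            else:
                j += 5
    return out


_CT_CLASS = {aa: ci for ci, cls in enumerate(P.CTRIAD_CLASSES) for aa in cls}

def ctriad(record: ProteinRecord) -> np.ndarray:
    """Conjoint triad: residues mapped to 7 classes (side-chain volume and
    dipole), frequency of each class triad over L-2 windows; 343 dims summing
    to 1 (raw frequency, stable across sequence lengths)."""
    seq = record.sequence
    if len(seq) < 3:
        raise SequenceLengthError(f"{record.id}: CTriad needs length >= 3, got {len(seq)}")
    v = np.zeros(343)
    for i in range(len(seq) - 2):
        a, b, c = (_CT_CLASS[x] for x in seq[i : i + 3])
        v[(a * 7 + b) * 7 + c] += 1
    return v / (len(seq) - 2)


def qsorder(
    record: ProteinRecord,
    lag: int = 10,
    w: float = 0.1,
    distance_matrix: np.ndarray | None = None,
) -> np.ndarray:
    """Quasi-sequence-order descriptor.

    With residue counts f_r and sequence-order coupling numbers
    tau_d = sum_i d(R_i, R_{i+d})^2 over a residue distance matrix:

        X_r      = f_r / (sum_r f_r + w * sum_d tau_d)        r = 1..20
        X_{20+d} = w * tau_d / (sum_r f_r + w * sum_d tau_d)  d = 1..lag

    The full vector sums to 1; with w=0 the first 20 entries reduce to plain
    amino-acid composition.
    """
    seq = record.sequence
    L = len(seq)
    if L <= lag:
        raise SequenceLengthError(f"{record.id}: QSOrder needs length > lag={lag}, got {L}")
    dm = P.load_distance_matrix() if distance_matrix is None else distance_matrix
    idx = np.array([P.AA_INDEX[aa] for aa in seq])
    f = np.bincount(idx, minlength=20).astype(float)
    tau = np.array([(dm[idx[: L - d], idx[d:]] ** 2).sum() for d in range(1, lag + 1)])
    denom = f.sum() + w * tau.sum()
    return np.concatenate([f / denom, w * tau / denom])


# ---------------------------------------------------------------------------
# Dataset-level featurization
# ---------------------------------------------------------------------------

def _tpc_names():
    return [f"TPC_{t}" for t in _TRIPEPTIDES]

def _gtpc_names():
    return [f"GTPC_{a}.{b}.{c}" for a in _GTPC_NAMES for b in _GTPC_NAMES for c in _GTPC_NAMES]

def _geary_names(scales=None, nlag=8):
    scales = P.GEARY_SCALES if scales is None else scales
    return [f"Geary_{s}_lag{d}" for s in scales for d in range(1, nlag + 1)]

def _ctdd_names():
    return [
        f"CTDD_{attr}_c{ci + 1}_{q}"
        for attr in P.CTD_ATTRIBUTES
        for ci in range(3)
        for q in ("first", "25pct", "50pct", "75pct", "100pct")
    ]

def _ctriad_names():
    return [f"CTriad_{a + 1}.{b + 1}.{c + 1}" for a in range(7) for b in range(7) for c in range(7)]

def _qsorder_names(lag=10, **_):
    return [f"QSOrder_comp_{aa}" for aa in P.AMINO_ACIDS] + [f"QSOrder_tau{d}" for d in range(1, lag + 1)]


FEATURIZERS = {
    "tpc": (tpc, _tpc_names),
    "gtpc": (gtpc, _gtpc_names),
    "geary": (geary, _geary_names),
    "ctdd": (ctdd, _ctdd_names),
    "ctriad": (ctriad, _ctriad_names),
    "qsorder": (qsorder, _qsorder_names),
}


def featurize_records(
    records: list[ProteinRecord], featurizer: str, **params
) -> FeatureMatrix:
    """Apply one named descriptor family to a list of records.

    Records too short for the family's preconditions are dropped with a
    warning; an empty surviving set is an error.
    """
    if featurizer not in FEATURIZERS:
        raise ValueError(f"unknown featurizer {featurizer!r}; choose from {sorted(FEATURIZERS)}")
    func, namer = FEATURIZERS[featurizer]
    if featurizer == "qsorder" and "distance_matrix" not in params:
        params = {**params, "distance_matrix": P.load_distance_matrix()}
    rows, ids = [], []
    for rec in records:
        try:
            rows.append(func(rec, **params))
            ids.append(rec.id)
        except SequenceLengthError as e:
            logger.warning("dropping %s from featurization: %s", rec.id, e)
    if not rows:
        raise ValueError(f"no records satisfy the length requirements of {featurizer!r}")
    name_params = {k: v for k, v in params.items() if k in ("nlag", "lag", "scales")}
    return FeatureMatrix(
        sample_ids=ids,
        feature_names=namer(**name_params),
        values=np.vstack(rows),
        provenance=f"descriptor:{featurizer}",
        params={k: v for k, v in params.items() if not isinstance(v, (np.ndarray, dict))},
    )


def featurize_dataset(dataset: LabeledDataset, featurizer: str, **params) -> FeatureMatrix:
    return featurize_records(dataset.records, featurizer, **params)


def concat_features(a: FeatureMatrix, b: FeatureMatrix) -> FeatureMatrix:
    """Horizontally concatenate two feature matrices over identical samples.

    Feature names are prefixed with each input's provenance so the combined
    name list stays unique.
    """
    if a.sample_ids != b.sample_ids:
        raise ValueError("sample ids differ (or are ordered differently); cannot concatenate")
    names = [f"{a.provenance}|{n}" for n in a.feature_names] + [
        f"{b.provenance}|{n}" for n in b.feature_names
    ]
    return FeatureMatrix(
        sample_ids=list(a.sample_ids),
        feature_names=names,
        values=np.hstack([a.values, b.values]),
        provenance=f"concat({a.provenance},{b.provenance})",
    )
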