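"""Uniform protein-embedding interface.

Three routes produce the per-protein embedding vectors the classifier
consumes:

* :func:`plm_adapter` — an adapter over an external protein language model
  (optional dependency; not bundled).
* :func:`load_precomputed` — a delimited table of embeddings computed
  elsewhere, so real language-model features can be plugged in offline.
* :class:`FixtureEmbedder` — a deterministic hashed k-mer embedder used by
  the test/benchmark pipeline; composition-sensitive so planted motifs are
  detectable, but carrying none of a language model's learned structure.

Plus the contact-map reduction: an n-by-m residue-residue contact-probability
matrix (ligase x target) is max-pooled along the target axis to a fixed
n-vector, one value per ligase residue, so targets of any length stack into a
rectangular feature matrix.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

from .descriptors import FeatureMatrix
from .sequence_io import ProteinRecord


@runtime_checkable
class Embedder(Protocol):
    """Contract: a deterministic map from a sequence to a fixed-length vector."""

    name: str
    dim: int

    def embed(self, sequence: str) -> np.ndarray: ...


class FixtureEmbedder:
    """Seeded hashed k-mer count embedder.

    Each k-mer of the sequence is hashed (BLAKE2b keyed by the seed, so the
    bucket assignment is stable across processes) into one of ``dim``
    buckets; bucket counts are L1-normalized. Pure function of the sequence.
    """

    def __init__(self, dim: int = 256, k: int = 3, seed: int = 0):
        if dim < 1:
            raise ValueError(f"dim must be >= 1, got {dim}")
        if not 1 <= k <= 4:
            raise ValueError(f"k must be in 1..4, got {k}")
        self.dim = dim
        self.k = k
        self.seed = seed
        self.name = f"fixture_kmer(k={k},dim={dim},seed={seed})"
        self._key = seed.to_bytes(8, "little")
        self._bucket_cache: dict[str, int] = {}

    def _bucket(self, kmer: str) -> int:
        b = self._bucket_cache.get(kmer)
        if b is None:
            h = hashlib.blake2b(kmer.encode(), key=self._key, digest_size=8)
            b = int.from_bytes(h.digest(), "little") % self.dim
            self._bucket_cache[kmer] = b
        return b

    def embed(self, sequence: str) -> np.ndarray:
        if len(sequence) < self.k:
            raise ValueError(f"sequence shorter than k={self.k}")
        v = np.zeros(self.dim)
        for i in range(len(sequence) - self.k + 1):
            v[self._bucket(sequence[i : i + self.k])] += 1.0
        return v / v.sum()


def plm_adapter(model_name: str = "esm1b_t33_650M_UR50S", pooling: str = "mean") -> Embedder:
    """Adapter over an external transformer protein language model.

    Requires the optional ``fair-esm``/``torch`` dependency; per-residue
    representations from the final layer are pooled to one vector (``mean``
    over positions by default, ``cls`` for the begin-of-sequence token).
    Sequences beyond the model's position limit are split into
    non-overlapping windows, embedded separately, and the window vectors
    averaged — deterministic and free of truncation bias.
    """
    if pooling not in ("mean", "cls"):
        raise ValueError(f"pooling must be 'mean' or 'cls', got {pooling!r}")
    try:
        import esm  # type: ignore
        import torch  # type: ignore
    except ImportError as e:
        raise ImportError(
            "The protein-language-model adapter needs the optional 'fair-esm' and "
            "'torch' packages, which are not installed. Offline alternatives: "
            "load precomputed embeddings with embedding.load_precomputed(), or use "
            "the deterministic embedding.FixtureEmbedder for testing."
        ) from e

    model, alphabet = esm.pretrained.load_model_and_alphabet(model_name)
    model.eval()
    converter = alphabet.get_batch_converter()
    n_layers = model.num_layers
    dim = model.embed_dim
    max_len = 1022  # positional-embedding limit of the 1b-scale models

    class _PLMEmbedder:
        def __init__(self):
            self.name = f"plm:{model_name}:{pooling}"
            self.dim = dim

        def _embed_window(self, seq: str) -> np.ndarray:
            _, _, toks = converter([("x", seq)])
            with torch.no_grad():
                out = model(toks, repr_layers=[n_layers])
            rep = out["representations"][n_layers][0]
            if pooling == "cls":
                return rep[0].numpy()
            return rep[1 : len(seq) + 1].mean(dim=0).numpy()

        def embed(self, sequence: str) -> np.ndarray:
            windows = [sequence[i : i + max_len] for i in range(0, len(sequence), max_len)]
            return np.mean([self._embed_window(w) for w in windows], axis=0)

    return _PLMEmbedder()


def embed_records(records: list[ProteinRecord], embedder: Embedder) -> FeatureMatrix:
    """Embed every record; provenance ``embedder:<name>`` marks the matrix as
    embedding-derived (required by the eSHAP feature-selection stage)."""
    rows, ids = [], []
    for r in records:
        rows.append(embedder.embed(r.sequence))
        ids.append(r.id)
    if not rows:
        raise ValueError("no records to embed")
    return FeatureMatrix(
        sample_ids=ids,
        feature_names=[f"emb_{i}" for i in range(embedder.dim)],
        values=np.vstack(rows),
        provenance=f"embedder:{embedder.name}",
    )


def load_precomputed(path: str | Path) -> FeatureMatrix:
    """Load precomputed embeddings from a delimited text table.

    Format: one row per protein, ``id`` followed by a fixed number of numeric
    columns (tab or comma separated; an optional header row is skipped).
    """
    path = Path(path)
    ids, rows = [], []
    width = None
    with open(path) as fh:
        for rowno, ln in enumerate(fh, start=1):
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.replace(",", "\t").split("\t")
            if rowno == 1 and len(parts) > 1:
                try:
                    float(parts[1])
                except ValueError:
                    continue  # header row
            try:
                vals = [float(x) for x in parts[1:]]
            except ValueError as e:
                raise ValueError(f"{path}:{rowno}: non-numeric cell ({e})") from None
            if width is None:
                width = len(vals)
                if width == 0:
                    raise ValueError(f"{path}:{rowno}: no numeric columns")
            elif len(vals) != width:
                raise ValueError(
                    f"{path}:{rowno}: ragged row ({len(vals)} values, expected {width})"
                )
            ids.append(parts[0])
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no embedding rows found")
    return FeatureMatrix(
        sample_ids=ids,
        feature_names=[f"emb_{i}" for i in range(width)],
        values=np.array(rows),
        provenance=f"embedder:precomputed:{path.name}",
    )


# ---------------------------------------------------------------------------
# Contact-matrix pooling
# ---------------------------------------------------------------------------

@dataclass
class ContactMatrix:
    """Residue-residue contact probabilities between an E3 ligase (rows, n)
    and a target protein (columns, m)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("contact matrix must be non-empty and 2-D")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("contact probabilities must lie in [0, 1]")

    @property
    def ligase_len(self) -> int:
        return self.values.shape[0]

    @property
    def target_len(self) -> int:
        return self.values.shape[1]


def maxpool_contacts(cm: ContactMatrix) -> np.ndarray:
    """Max-pool the target axis: entry i is the highest contact probability
    of ligase residue i with any target residue. Output length equals the
    ligase length, so vectors for different targets are directly stackable."""
    return cm.values.max(axis=1)


def read_contact_matrix(path: str | Path) -> ContactMatrix:
    """Read a dense contact matrix: a ``n<TAB>m`` shape header line followed
    by n whitespace-delimited rows of m probabilities."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: expected a two-integer shape header")
        n, m = int(header[0]), int(header[1])
        mat = np.loadtxt(fh, ndmin=2)
    if mat.shape != (n, m):
        raise ValueError(f"{path}: data shape {mat.shape} != declared ({n}, {m})")
    return ContactMatrix(values=mat)
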