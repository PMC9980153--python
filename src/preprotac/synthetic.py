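"""Synthetic labeled sequence cohorts with a planted, position-localized signal.

Real degradability labels come from degrader screens and cannot be bundled;
to make every pipeline stage testable offline, this module generates random
protein sequences in which a short motif is inserted with class-conditional
probability. The motif plays the role of the sequence property separating
degradable from non-degradable proteins, and its known coordinates let tests
check that the eSHAP scan points back to the right residues.

What this emulates: the size and class balance of a curated kinase
degradation panel, a learnable sequence-level signal, and per-residue ground
truth. What it does not emulate: kinase domain architecture, homology
structure between samples, or anything a structure-aware embedder would see.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .properties import AMINO_ACIDS
from .sequence_io import LabeledDataset, ProteinRecord

#: Benchmark cohort defaults: 200/234 class split (matching the ~200 CRBN-degraded
#: vs 234 non-degraded proteins of a published kinase degradation panel),
#: kinase-like length range, and a 6-residue motif planted in every positive
#: and, as background noise, in 2% of negatives.
BENCHMARK = dict(
    n_pos=200,
    n_neg=234,
    length_range=(80, 300),
    motif="WCKDHE",
    insertion_prob_pos=1.0,
    insertion_prob_neg=0.02,
)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic cohort."""

    n_pos: int
    n_neg: int
    length_range: tuple[int, int]
    motif: str
    motif_site: int | str = "random"  # fixed 1-based start, or random interior
    insertion_prob_pos: float = 1.0
    insertion_prob_neg: float = 0.0
    background: dict[str, float] | None = None  # None -> uniform over 20 residues
    seed: int = 0

    def __post_init__(self) -> None:
        if not set(self.motif) <= set(AMINO_ACIDS):
            raise ValueError("motif must use canonical residues")
        lo, hi = self.length_range
        if len(self.motif) > lo:
            raise ValueError(
                f"motif length {len(self.motif)} exceeds minimum sequence length {lo}"
            )
        if not 0 <= self.insertion_prob_neg <= self.insertion_prob_pos <= 1:
            raise ValueError(
                "need 0 <= insertion_prob_neg <= insertion_prob_pos <= 1 for a learnable signal"
            )
        if self.background is not None:
            if set(self.background) != set(AMINO_ACIDS):
                raise ValueError("background table must cover the 20 canonical residues")
            if abs(sum(self.background.values()) - 1.0) > 1e-9:
                raise ValueError("background frequencies must sum to 1")


def generate(spec: SyntheticSpec) -> tuple[LabeledDataset, dict[str, list[int]]]:
    """Generate a labeled cohort and the ground-truth motif coordinates.

    Sequences are i.i.d. from the background distribution; the motif
    overwrites a window starting at ``motif_site`` (or a random interior
    site) with probability ``insertion_prob_pos`` / ``insertion_prob_neg``
    depending on the class. Returns the dataset and a map
    id -> 1-based motif positions ([] when the motif was not inserted).
    Byte-identical output for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    aas = np.array(list(AMINO_ACIDS))
    probs = (
        None
        if spec.background is None
        else np.array([spec.background[a] for a in AMINO_ACIDS])
    )
    lo, hi = spec.length_range
    mlen = len(spec.motif)

    records: list[ProteinRecord] = []
    labels: dict[str, int] = {}
    truth: dict[str, list[int]] = {}
    plan = [(1, i, spec.insertion_prob_pos) for i in range(spec.n_pos)] + [
        (0, i, spec.insertion_prob_neg) for i in range(spec.n_neg)
    ]
    for label, i, p_insert in plan:
        rid = f"{'pos' if label else 'neg'}_{i:04d}"
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(aas, size=L, p=probs))
        positions: list[int] = []
        if rng.random() < p_insert:
            if spec.motif_site == "random":
                # interior placement: avoid the first and last residue when possible
                start = int(rng.integers(1, max(L - mlen - 1, 1) + 1))
            else:
                start = int(spec.motif_site) - 1
                if start < 0 or start + mlen > L:
                    raise ValueError(f"fixed motif site {spec.motif_site} out of range for length {L}")
            seq = seq[:start] + spec.motif + seq[start + mlen :]
            positions = list(range(start + 1, start + 1 + mlen))
        records.append(ProteinRecord(id=rid, sequence=seq))
        labels[rid] = label
        truth[rid] = positions
    return LabeledDataset(records=records, labels=labels), truth


def default_benchmark(seed: int = 0) -> tuple[LabeledDataset, dict[str, list[int]]]:
    """The canonical offline benchmark cohort (434 proteins, planted 6-mer)."""
    return generate(SyntheticSpec(seed=seed, **BENCHMARK))


def write_truth(truth: dict[str, list[int]], path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))
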