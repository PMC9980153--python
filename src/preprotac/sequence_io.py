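"""FASTA / label-table I/O, residue validation and point-mutant generation.

Positions are 1-based everywhere they are user-visible, matching residue
numbering conventions in the structural literature (e.g. "Lys454").
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .properties import AA_SET, OPPOSITE_RESIDUE

logger = logging.getLogger(__name__)

ResiduePolicy = Literal["error", "drop", "replace"]


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (bad header, empty or duplicate entry)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One validated protein sequence.

    ``sequence`` is uppercase over the 20 canonical residues; position ``i``
    of the protein is ``sequence[i - 1]`` (1-based indexing in all reports).
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - AA_SET
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-canonical residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """Protein records joined to binary degradability labels.

    Label 1 means the protein is degraded by a CRBN-recruiting degrader,
    0 means it is not.
    """

    records: list[ProteinRecord]
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate record ids in dataset")
        missing = [i for i in ids if i not in self.labels]
        if missing:
            raise ValueError(f"records without labels: {missing[:5]}")
        for rid, lab in self.labels.items():
            if lab not in (0, 1):
                raise ValueError(f"label for {rid!r} must be 0 or 1, got {lab!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def y(self) -> list[int]:
        return [self.labels[r.id] for r in self.records]

    def class_counts(self) -> tuple[int, int]:
        y = self.y
        return y.count(1), y.count(0)


class Mutant(NamedTuple):
    position: int  # 1-based
    ref_aa: str
    alt_aa: str
    sequence: str


@dataclass
class MutantSet:
    """Single-residue property-opposite mutants of one parent sequence."""

    parent_id: str
    parent_sequence: str
    mutants: list[Mutant]

    def __len__(self) -> int:
        return len(self.mutants)


def _sanitize(seq: str, rid: str, policy: ResiduePolicy, replacement: str) -> str | None:
    """Apply the non-canonical-residue policy; None means drop the record."""
    seq = seq.upper().replace("*", "")
    bad = set(seq) - AA_SET
    if not bad:
        return seq
    if policy == "error":
        raise FastaParseError(f"record {rid!r}: non-canonical residues {sorted(bad)}")
    if policy == "drop":
        logger.warning("dropping record %s: non-canonical residues %s", rid, sorted(bad))
        return None
    logger.warning(
        "record %s: replacing non-canonical residues %s with %r", rid, sorted(bad), replacement
    )
    return "".join(c if c in AA_SET else replacement for c in seq)


def read_fasta(
    path: str | Path,
    residue_policy: ResiduePolicy = "drop",
    replacement: str = "A",
) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into validated :class:`ProteinRecord` s.

    Sequences are uppercased and wrapped lines joined; a trailing ``*`` stop
    is stripped. ``residue_policy`` controls non-canonical letters (X, U, B,
    Z, ...): ``"error"`` aborts, ``"drop"`` skips the record with a warning
    (suits training data), ``"replace"`` substitutes ``replacement`` with a
    warning (suits large-scale screening, which must not abort on one odd
    letter).
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        raise FastaParseError(f"{path}: not FASTA (first non-blank character is not '>')")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for sr in SeqIO.parse(str(path), "fasta"):
        if not sr.id:
            raise FastaParseError(f"{path}: entry with empty header")
        if sr.id in seen:
            raise FastaParseError(f"{path}: duplicate id {sr.id!r}")
        seen.add(sr.id)
        if len(sr.seq) == 0:
            raise FastaParseError(f"{path}: entry {sr.id!r} has an empty sequence")
        seq = _sanitize(str(sr.seq), sr.id, residue_policy, replacement)
        if seq is None or not seq:
            continue
        desc = sr.description[len(sr.id):].strip() if sr.description.startswith(sr.id) else sr.description
        records.append(ProteinRecord(id=sr.id, sequence=seq, description=desc))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA; round-trips ids and sequences exactly."""
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id}" + (f" {r.description}" if r.description else "")
            fh.write(header + "\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i : i + width] + "\n")


def read_labels(path: str | Path, records: list[ProteinRecord]) -> LabeledDataset:
    """Join a two-column id/label table (CSV or TSV, optional header) to records.

    Records without a label are excluded with a logged count; labels outside
    {0, 1} raise; zero overlap between the table and the records raises.
    """
    path = Path(path)
    labels: dict[str, int] = {}
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        try:
            dialect = csv.Sniffer().sniff(sample, delimiters=",\t")
        except csv.Error:
            dialect = csv.excel_tab
        for rowno, row in enumerate(csv.reader(fh, dialect), start=1):
            if not row or not row[0].strip():
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{rowno}: expected two columns, got {row!r}")
            rid, raw = row[0].strip(), row[1].strip()
            if rowno == 1 and raw.lower() in ("label", "labels", "y", "class"):
                continue  # single header row
            if raw not in ("0", "1"):
                raise ValueError(f"{path}:{rowno}: label must be 0 or 1, got {raw!r}")
            labels[rid] = int(raw)
    kept = [r for r in records if r.id in labels]
    n_dropped = len(records) - len(kept)
    if not kept:
        raise ValueError(f"{path}: no overlap between label table and records")
    if n_dropped:
        logger.warning("%d records without labels excluded", n_dropped)
    return LabeledDataset(records=kept, labels={r.id: labels[r.id] for r in kept})


def write_labels(dataset: LabeledDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in dataset.records:
            fh.write(f"{r.id}\t{dataset.labels[r.id]}\n")


def opposite_residue(aa: str, table: dict[str, str] | None = None) -> str:
    """Return the opposite-property substitute for a canonical residue.

    The default table flips charge (K/R/H to E/E/D, D/E to K), sends polar
    residues to hydrophobic ones and vice versa, and swaps P/G; it is total
    over the alphabet and never maps a residue to itself.
    """
    table = OPPOSITE_RESIDUE if table is None else table
    if aa not in AA_SET:
        raise ValueError(f"non-canonical residue {aa!r}")
    return table[aa]


def scan_mutants(record: ProteinRecord, table: dict[str, str] | None = None) -> MutantSet:
    """Generate the full single-residue property-opposite mutant set.

    One mutant per position: position ``i`` (1-based) carries
    ``opposite_residue(sequence[i-1])`` and is otherwise identical to the
    parent, so every mutant is Hamming distance 1 from it.
    """
    seq = record.sequence
    mutants = []
    for i, ref in enumerate(seq, start=1):
        alt = opposite_residue(ref, table)
        mutants.append(Mutant(i, ref, alt, seq[: i - 1] + alt + seq[i:]))
    return MutantSet(parent_id=record.id, parent_sequence=seq, mutants=mutants)


def write_mutants_fasta(mutset: MutantSet, path: str | Path) -> None:
    """Write a MutantSet as FASTA with ids ``{parent}_{pos}{ref}>{alt}``."""
    recs = [
        SeqRecord(Seq(m.sequence), id=f"{mutset.parent_id}_{m.position}{m.ref_aa}>{m.alt_aa}", description="")
        for m in mutset.mutants
    ]
    SeqIO.write(recs, str(path), "fasta")
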