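"""FASTA input/output, residue validation, and labeled two-class datasets.

Sequences are validated against the 20 standard one-letter amino-acid codes.
Ambiguous residues (B, J, O, U, X, Z) — as well as stop characters (``*``),
whitespace, and anything else outside the standard alphabet — make a sequence
invalid; validation reports each offending character with its 1-based position
rather than silently stripping it.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "STANDARD_AA",
    "AMBIGUOUS_AA",
    "ProteinSequence",
    "ValidationReport",
    "LabeledDataset",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "validate_sequence",
    "load_labeled_dataset",
    "load_labeled_dataset_from_table",
]

log = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by one-letter code.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguous/non-standard residue codes excluded from analysis.
AMBIGUOUS_AA = "BJOUXZ"

_VALID = frozenset(STANDARD_AA)


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (names the offending line)."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with identifier; residues are uppercase letters."""

    id: str
    residues: str

    @property
    def L(self) -> int:
        """Sequence length (number of residues)."""
        return len(self.residues)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.residues)


@dataclass
class ValidationReport:
    """Offending characters of an invalid sequence, with 1-based positions."""

    seq_id: str
    offenses: list[tuple[int, str]] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.offenses

    def __str__(self) -> str:
        if self.valid:
            return f"{self.seq_id}: valid"
        items = ", ".join(f"{c!r}@{p}" for p, c in self.offenses)
        return f"{self.seq_id}: {len(self.offenses)} invalid residue(s): {items}"


@dataclass
class LabeledDataset:
    """Parallel sequences and binary labels (1 = positive class = enzyme)."""

    sequences: list[ProteinSequence]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sequences) != len(self.labels):
            raise ValueError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be 0/1, got extra values {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return len(self) - self.n_pos

    def require_both_classes(self) -> None:
        if self.n_pos == 0 or self.n_neg == 0:
            raise ValueError(
                f"both classes must be non-empty (positives={self.n_pos}, "
                f"negatives={self.n_neg})"
            )


def validate_sequence(
    seq: ProteinSequence,
) -> Union[ProteinSequence, ValidationReport]:
    """Return *seq* unchanged if every residue is standard, else a report.

    The report lists each offending character with its 1-based position.
    """
    offenses = [
        (pos, ch)
        for pos, ch in enumerate(seq.residues, start=1)
        if ch not in _VALID
    ]
    if offenses:
        return ValidationReport(seq_id=seq.id, offenses=offenses)
    return seq


def _check_leading_header(path: Path) -> None:
    """Fail early, naming the line, if the file does not open with '>'."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header starting "
                    f"with '>', got {line.strip()[:30]!r}"
                )
            return
    raise FastaParseError(f"{path}: file contains no FASTA records")


def read_fasta(path: Union[str, Path]) -> list[ProteinSequence]:
    """Read a FASTA file into ``ProteinSequence`` records.

    Line wrapping is removed, residues are uppercased (lowercase input is
    logged), and input order is preserved.  Records with empty sequences and
    files that do not start with a header raise :class:`FastaParseError`.
    Duplicate ids are permitted but logged; downstream rows are keyed by
    position, never by id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_leading_header(path)

    out: list[ProteinSequence] = []
    n_lower = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if not raw:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        if raw != raw.upper():
            n_lower += 1
        out.append(ProteinSequence(id=rec.id, residues=raw.upper()))
    if n_lower:
        log.info("%s: uppercased %d record(s) containing lowercase residues", path, n_lower)
    dupes = [i for i, c in Counter(s.id for s in out).items() if c > 1]
    if dupes:
        log.warning("%s: duplicate FASTA ids (rows keyed by position): %s", path, dupes[:5])
    return out


def write_fasta(
    sequences: Iterable[ProteinSequence], path: Union[str, Path], width: int = 60
) -> None:
    """Write sequences to FASTA, wrapping lines at *width* residues."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(records)


def _partition_valid(
    seqs: Sequence[ProteinSequence], source: str, on_invalid: str
) -> list[ProteinSequence]:
    if on_invalid not in ("drop", "fail"):
        raise ValueError(f"on_invalid must be 'drop' or 'fail', got {on_invalid!r}")
    kept: list[ProteinSequence] = []
    reports: list[ValidationReport] = []
    for s in seqs:
        res = validate_sequence(s)
        if isinstance(res, ValidationReport):
            reports.append(res)
        else:
            kept.append(res)
    if reports:
        if on_invalid == "fail":
            raise ValueError(
                f"{source}: {len(reports)} invalid sequence(s); first: {reports[0]}"
            )
        log.info("%s: dropped %d invalid sequence(s)", source, len(reports))
    return kept


def load_labeled_dataset(
    pos_path: Union[str, Path],
    neg_path: Union[str, Path],
    on_invalid: str = "drop",
) -> LabeledDataset:
    """Load a two-file labeled dataset (positives = enzymes, label 1).

    Invalid sequences are dropped with a logged count, or abort the load,
    per *on_invalid* ∈ {'drop', 'fail'}.  Either class ending up empty after
    filtering is an error.
    """
    pos = _partition_valid(read_fasta(pos_path), str(pos_path), on_invalid)
    neg = _partition_valid(read_fasta(neg_path), str(neg_path), on_invalid)
    if not pos:
        raise ValueError(f"{pos_path}: no valid positive sequences remain")
    if not neg:
        raise ValueError(f"{neg_path}: no valid negative sequences remain")
    labels = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    return LabeledDataset(sequences=pos + neg, labels=labels)


def load_labeled_dataset_from_table(
    fasta_path: Union[str, Path],
    labels_path: Union[str, Path],
    on_invalid: str = "drop",
) -> LabeledDataset:
    """Load a single FASTA plus a two-column TSV label file (id, label∈{1,0}).

    Every record in the FASTA must have a label; order follows the FASTA.
    """
    seqs = read_fasta(fasta_path)
    table: dict[str, int] = {}
    with open(labels_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in ("0", "1"):
                raise ValueError(
                    f"{labels_path}: line {lineno}: expected 'id<TAB>0|1', got {line!r}"
                )
            table[parts[0]] = int(parts[1])
    missing = [s.id for s in seqs if s.id not in table]
    if missing:
        raise ValueError(f"{labels_path}: no label for ids {missing[:5]}")
    kept = _partition_valid(seqs, str(fasta_path), on_invalid)
    labels = np.array([table[s.id] for s in kept], dtype=int)
    ds = LabeledDataset(sequences=kept, labels=labels)
    ds.require_both_classes()
    return ds
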