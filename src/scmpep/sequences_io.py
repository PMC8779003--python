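"""Peptide sequence I/O and labeled-dataset containers.

Peptides are short amino-acid sequences (tumor-homing peptides span roughly
3-30 residues) over the 20-letter standard alphabet. Input may be FASTA or a
bare one-sequence-per-line list, the format the public THP benchmark sets are
distributed in; the two dialects are auto-detected by the presence of a '>'
header.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

STANDARD_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"
_RESIDUE_SET = frozenset(STANDARD_RESIDUES)

logger = logging.getLogger(__name__)


class SequenceValidationError(ValueError):
    """Raised when a record contains characters outside the 20 standard residues."""


@dataclass(frozen=True)
class Peptide:
    """A validated peptide sequence with an optional binary activity label.

    label 1 marks the positive (tumor-homing) class, 0 the negative class.
    """

    id: str
    seq: str
    label: int | None = None

    def __post_init__(self) -> None:
        validate_sequence(self.seq, record=self.id)
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.seq)

    def with_label(self, label: int) -> "Peptide":
        return Peptide(self.id, self.seq, label)


def validate_sequence(seq: str, record: str = "<unnamed>") -> str:
    """Check that *seq* is non-empty uppercase over the 20 standard residues.

    Ambiguity codes (B, J, O, U, X, Z), gaps and stops are rejected: the
    scoring card assigns propensities to the 20 standard residues only.
    """
    if not seq:
        raise SequenceValidationError(f"record {record!r}: empty sequence")
    for ch in seq:
        if ch not in _RESIDUE_SET:
            raise SequenceValidationError(
                f"record {record!r}: invalid residue {ch!r} "
                f"(allowed: {STANDARD_RESIDUES})"
            )
    return seq


@dataclass
class LabeledDataset:
    """Ordered collection of labeled peptides supporting stratified splitting.

    Iteration order is stable so seeded fold assignment is reproducible.
    """

    peptides: list[Peptide]
    name: str = "dataset"

    def __post_init__(self) -> None:
        for p in self.peptides:
            if p.label not in (0, 1):
                raise ValueError(f"peptide {p.id!r} has no binary label")

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, i):
        return self.peptides[i]

    @property
    def n_positive(self) -> int:
        return sum(1 for p in self.peptides if p.label == 1)

    @property
    def n_negative(self) -> int:
        return sum(1 for p in self.peptides if p.label == 0)

    @property
    def labels(self) -> list[int]:
        return [p.label for p in self.peptides]  # type: ignore[misc]

    @property
    def sequences(self) -> list[str]:
        return [p.seq for p in self.peptides]

    def subset(self, indices: Sequence[int], name: str | None = None) -> "LabeledDataset":
        return LabeledDataset([self.peptides[i] for i in indices],
                              name=name or self.name)


def _parse_fasta_text(text: str, label: int | None) -> list[Peptide]:
    peptides: list[Peptide] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper()
        validate_sequence(seq, record=header)
        peptides.append(Peptide(header, seq, label))

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].split()[0] if line[1:].strip() else f"seq{len(peptides) + 1}"
            chunks = []
        else:
            if header is None:
                raise SequenceValidationError("sequence data before first FASTA header")
            chunks.append(line)
    flush()
    return peptides


def _parse_plain_text(text: str, label: int | None) -> list[Peptide]:
    peptides = []
    for i, line in enumerate(text.splitlines()):
        line = line.strip()
        if not line:
            continue
        seq = line.upper()
        rec_id = f"seq{len(peptides) + 1}"
        validate_sequence(seq, record=rec_id)
        peptides.append(Peptide(rec_id, seq, label))
    return peptides


def read_fasta(source: str | Path, label: int | None = None) -> list[Peptide]:
    """Read peptides from FASTA or plain one-sequence-per-line text.

    Parameters
    ----------
    source
        Path to a file, or the text itself (anything containing a newline or
        a '>' is treated as text; otherwise it is tried as a path first).
    label
        Optional binary label applied to every record.

    The dialect is auto-detected: text containing '>' is parsed as FASTA,
    otherwise each non-blank line is one peptide with an auto-generated id.
    Lowercase input is uppercased before validation.
    """
    text: str
    if isinstance(source, Path):
        text = source.read_text()
    else:
        candidate = Path(source) if ("\n" not in source and ">" not in source) else None
        if candidate is not None and candidate.is_file():
            text = candidate.read_text()
        else:
            text = source
    if not text.strip():
        raise SequenceValidationError("empty input: no sequences found")
    if ">" in text:
        peptides = _parse_fasta_text(text, label)
    else:
        peptides = _parse_plain_text(text, label)
    if not peptides:
        raise SequenceValidationError("empty input: no sequences found")
    return peptides


def write_fasta(peptides: Iterable[Peptide], path: str | Path | None = None) -> str:
    """Serialize peptides as FASTA; returns the text, optionally writing *path*."""
    text = "".join(f">{p.id}\n{p.seq}\n" for p in peptides)
    if path is not None:
        Path(path).write_text(text)
    return text


def build_dataset(positives: list[Peptide], negatives: list[Peptide],
                  name: str = "dataset") -> LabeledDataset:
    """Merge positive and negative peptides into a labeled dataset.

    Labels are forced (1 for positives, 0 for negatives) regardless of any
    label on the inputs. Duplicate sequences are permitted — the public
    benchmarks contain repeats — but counted in a summary log message.
    """
    if not positives:
        raise ValueError("positives list is empty")
    if not negatives:
        raise ValueError("negatives list is empty")
    members = [p.with_label(1) for p in positives] + [n.with_label(0) for n in negatives]
    counts = Counter(p.seq for p in members)
    n_dup = sum(c - 1 for c in counts.values() if c > 1)
    if n_dup:
        logger.info("dataset %s: %d duplicate sequence occurrences retained", name, n_dup)
    return LabeledDataset(members, name=name)


def write_manifest(dataset: LabeledDataset, path: str | Path | None = None) -> str:
    """Tab-separated manifest (id, sequence, label) for a labeled dataset."""
    lines = ["id\tsequence\tlabel"]
    lines += [f"{p.id}\t{p.seq}\t{p.label}" for p in dataset]
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
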