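"""FASTA input/output and sequence-validity rules.

Training data for toxicity prediction comes as plain multi-FASTA files of
toxin-labelled positives and non-toxin negatives.  Cleaning enforces the
dataset rules used throughout the pipeline: a minimum length of 35
residues and the 20-letter standard alphabet (records containing the
ambiguous codes B, J, O, U, X or Z are rejected, not repaired).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal

from ._aadata import ALPHABET

_VALID = set(ALPHABET)

#: Minimum sequence length retained during cleaning.
MIN_LENGTH = 35


class FastaParseError(ValueError):
    """Raised for structurally invalid FASTA input; carries the line number."""


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence.

    ``id`` is the first whitespace-delimited token of the FASTA header,
    ``description`` the remainder of the header line.
    """

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass
class Dataset:
    """An ordered, uniquely-identified collection of records with one label."""

    records: list[ProteinRecord]
    label: Literal["toxin", "non-toxin", "unlabelled"] = "unlabelled"

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate record id {dup!r} in dataset")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


@dataclasses.dataclass(frozen=True)
class Rejection:
    id: str
    reason: str


def read_fasta(path: str | Path, label: str = "unlabelled") -> Dataset:
    """Parse a FASTA file into a :class:`Dataset`, preserving record order.

    Multi-line sequence bodies are concatenated.  Structural problems
    (empty file, sequence data before the first header, a header with an
    empty id, duplicate ids) raise :class:`FastaParseError` naming the
    offending line.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    header_line = 0
    current_id: str | None = None
    current_desc = ""
    chunks: list[str] = []

    def flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(
                f"{path}: record {current_id!r} (line {header_line}) has no sequence"
            )
        records.append(ProteinRecord(current_id, seq, current_desc))

    with open(path) as fh:
        saw_any = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            saw_any = True
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"{path}: empty header at line {lineno}")
                parts = header.split(None, 1)
                current_id = parts[0]
                current_desc = parts[1] if len(parts) > 1 else ""
                header_line = lineno
                chunks = []
            else:
                if current_id is None:
                    raise FastaParseError(
                        f"{path}: sequence data before first header at line {lineno}"
                    )
                chunks.append(line)
        if not saw_any:
            raise FastaParseError(f"{path}: empty FASTA (line 1)")
    flush()
    return Dataset(records, label=label)  # Dataset enforces id uniqueness


def write_fasta(ds: Dataset | Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA; inverse of :func:`read_fasta`."""
    records = ds.records if isinstance(ds, Dataset) else list(ds)
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def clean_sequences(
    ds: Dataset, min_len: int = MIN_LENGTH
) -> tuple[Dataset, list[Rejection]]:
    """Apply the validity rules, returning the kept records and a rejection log.

    Rules, in order per record: uppercase; strip a terminal ``*`` stop
    character; reject if any residue is outside the 20-letter alphabet
    (reason ``nonstandard residue``); reject if shorter than ``min_len``
    (reason ``length<N``).  Idempotent, and
    ``len(input) == len(output) + len(log)``.
    """
    kept: list[ProteinRecord] = []
    log: list[Rejection] = []
    for rec in ds:
        seq = rec.sequence.upper().rstrip("*")
        bad = set(seq) - _VALID
        if bad:
            log.append(Rejection(rec.id, "nonstandard residue"))
            continue
        if len(seq) < min_len:
            log.append(Rejection(rec.id, f"length<{min_len}"))
            continue
        kept.append(ProteinRecord(rec.id, seq, rec.description))
    return Dataset(kept, label=ds.label), log


def write_rejection_log(log: list[Rejection], path: str | Path) -> None:
    """Persist a rejection log as two-column TSV (id, reason)."""
    with open(path, "w") as fh:
        fh.write("id\treason\n")
        for item in log:
            fh.write(f"{item.id}\t{item.reason}\n")
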