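"""Evolutionary-profile features from PSI-BLAST position-specific matrices.

A PSSM holds one row per residue position and twenty log-odds columns.
Profiles are compressed to a fixed 20-vector by global average pooling
(GAP): the column-wise mean over positions.  Three providers supply
matrices: a live ``psiblast`` wrapper, a directory of precomputed ASCII
matrices keyed by sequence id, and a deterministic fallback that builds
a pseudo-profile from BLOSUM62 rows — useful when no sequence database
is available; its provenance is flagged on the matrix.
"""

from __future__ import annotations

import dataclasses
import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from ._aadata import ALPHABET, PSIBLAST_COLUMN_ORDER
from .sequence_io import ProteinRecord, write_fasta

__all__ = [
    "PSSMatrix",
    "parse_pssm",
    "format_pssm",
    "gap_pool",
    "run_psiblast",
    "PsiBlastProvider",
    "PrecomputedPSSMProvider",
    "FallbackPSSMProvider",
]

#: Feature names, alphabetical residue order.
GAP_FEATURE_NAMES = [f"PSSM_{aa}" for aa in ALPHABET]

# column j of the parsed matrix (native order) -> position in alphabet order
_NATIVE_TO_ALPHA = np.array(
    [ALPHABET.index(aa) for aa in PSIBLAST_COLUMN_ORDER]
)


@dataclasses.dataclass
class PSSMatrix:
    """L x 20 position-specific score matrix.

    ``scores`` keeps PSI-BLAST's native column order (``ARNDCQEGHILKMFPSTWYV``);
    ``source`` records provenance (``psiblast``, ``precomputed`` or
    ``fallback``).
    """

    id: str
    scores: np.ndarray
    source: str = "precomputed"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(f"PSSM for {self.id!r} must be L x 20")
        if self.scores.shape[0] < 1:
            raise ValueError(f"PSSM for {self.id!r} is empty")


def parse_pssm(ascii_text: str, id: str = "", source: str = "precomputed") -> PSSMatrix:
    """Parse the ``psiblast -out_ascii_pssm`` layout.

    Data rows carry the position, the query residue, twenty log-odds
    score columns and twenty weighted-percentage columns; only the score
    block is kept.  Header and footer lines are ignored.
    """
    rows = []
    for line in ascii_text.splitlines():
        parts = line.split()
        if len(parts) >= 42 and parts[0].isdigit() and len(parts[1]) == 1:
            try:
                rows.append([float(v) for v in parts[2:22]])
            except ValueError as exc:
                raise ValueError(f"malformed PSSM row: {line!r}") from exc
    if not rows:
        raise ValueError("no PSSM rows found in input")
    return PSSMatrix(id=id, scores=np.array(rows), source=source)


def format_pssm(p: PSSMatrix, query: str | None = None) -> str:
    """Render a matrix back into the ASCII dialect `parse_pssm` reads."""
    header = "    " + "  ".join(PSIBLAST_COLUMN_ORDER)
    lines = ["", "Last position-specific scoring matrix computed", header + "  " + header]
    for i, row in enumerate(p.scores, start=1):
        aa = query[i - 1] if query else "X"
        score_cols = " ".join(f"{int(v) if float(v).is_integer() else v:>3}" for v in row)
        pct_cols = " ".join("0" for _ in range(20))
        lines.append(f"{i:>5} {aa}  {score_cols}  {pct_cols}  0.00 0.00")
    return "\n".join(lines) + "\n"


def gap_pool(p: PSSMatrix) -> pd.Series:
    """Global average pooling: per-residue column means, alphabet order.

    ``GAP_j = (1/L) * sum_i P[i, j]``; linear in the matrix, and each
    pooled value lies between its column's min and max.
    """
    means = p.scores.mean(axis=0)
    out = np.empty(20)
    out[_NATIVE_TO_ALPHA] = means
    return pd.Series(out, index=GAP_FEATURE_NAMES)


def run_psiblast(
    record: ProteinRecord,
    database: str | Path,
    evalue: float = 0.001,
    iterations: int = 3,
    executable: str = "psiblast",
) -> PSSMatrix:
    """Run PSI-BLAST against a formatted database and parse the ASCII PSSM.

    Raises ``RuntimeError`` with remediation hints when the executable is
    missing or the search yields no usable profile (callers can fall back
    to :class:`PrecomputedPSSMProvider` or :class:`FallbackPSSMProvider`).
    """
    if shutil.which(executable) is None:
        raise RuntimeError(
            f"{executable!r} not found on PATH; supply precomputed ASCII PSSMs "
            "(PrecomputedPSSMProvider) or use the deterministic fallback "
            "(FallbackPSSMProvider)"
        )
    with tempfile.TemporaryDirectory() as tmp:
        query = Path(tmp) / "query.fasta"
        out_pssm = Path(tmp) / "out.pssm"
        write_fasta([record], query)
        cmd = [
            executable,
            "-query", str(query),
            "-db", str(database),
            "-evalue", str(evalue),
            "-num_iterations", str(iterations),
            "-out_ascii_pssm", str(out_pssm),
            "-num_threads", "1",
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0 or not out_pssm.exists():
            raise RuntimeError(
                f"psiblast failed for {record.id!r}: {proc.stderr.strip() or 'no PSSM produced'}"
            )
        return parse_pssm(out_pssm.read_text(), id=record.id, source="psiblast")


class PsiBlastProvider:
    """Live PSI-BLAST provider; falls back per sequence only on request."""

    def __init__(self, database: str | Path, evalue: float = 0.001, iterations: int = 3):
        self.database = database
        self.evalue = evalue
        self.iterations = iterations

    def get(self, record: ProteinRecord) -> PSSMatrix:
        return run_psiblast(record, self.database, self.evalue, self.iterations)


class PrecomputedPSSMProvider:
    """Serve ASCII PSSMs from a directory of ``<id>.pssm`` files."""

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)

    def get(self, record: ProteinRecord) -> PSSMatrix:
        path = self.directory / f"{record.id}.pssm"
        if not path.exists():
            raise FileNotFoundError(f"no precomputed PSSM for {record.id!r} at {path}")
        return parse_pssm(path.read_text(), id=record.id)


class FallbackPSSMProvider:
    """Deterministic pseudo-profile from BLOSUM62 substitution rows.

    Each position's 20 scores are the BLOSUM62 row of the residue at
    that position — a homology-free stand-in for a real search profile,
    flagged ``source='fallback'``.
    """

    def __init__(self) -> None:
        blosum = substitution_matrices.load("BLOSUM62")
        self._rows = {
            aa: np.array([float(blosum[aa][bb]) for bb in PSIBLAST_COLUMN_ORDER])
            for aa in ALPHABET
        }

    def get(self, record: ProteinRecord) -> PSSMatrix:
        scores = np.stack([self._rows[aa] for aa in record.sequence])
        return PSSMatrix(id=record.id, scores=scores, source="fallback")
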