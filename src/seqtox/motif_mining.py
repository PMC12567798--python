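"""Discriminative minimotif mining and one-hot encoding.

A minimotif here is a short literal substring present in at least one
toxin training sequence and absent from every non-toxin training
sequence.  Discovery is exhaustive over substring lengths in
``[min_len, max_len]``; motifs are ranked by how many positive
sequences contain them (coverage), ties broken by shorter length then
lexicographic order.  Because motifs are learned from labels, mining
must run inside the training portion of each cross-validation fold.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from .sequence_io import Dataset

__all__ = ["MotifSet", "discover_motifs", "encode_motifs"]


@dataclasses.dataclass
class MotifSet:
    """Ordered discriminative motifs with positive-coverage counts."""

    motifs: list[str]
    coverage: dict[str, int]

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def feature_names(self) -> list[str]:
        return [f"motif_{m}" for m in self.motifs]

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for m in self.motifs:
                fh.write(f"{m}\t{self.coverage[m]}\n")

    @classmethod
    def load(cls, path: str | Path) -> "MotifSet":
        motifs, coverage = [], {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            m, cov = line.split("\t")
            motifs.append(m)
            coverage[m] = int(cov)
        return cls(motifs, coverage)


def _substrings(seq: str, min_len: int, max_len: int) -> set[str]:
    out: set[str] = set()
    L = len(seq)
    for k in range(min_len, max_len + 1):
        for i in range(L - k + 1):
            out.add(seq[i : i + k])
    return out


def discover_motifs(
    pos: Dataset,
    neg: Dataset,
    max_len: int = 6,
    min_len: int = 3,
    top_k: int = 50,
) -> MotifSet:
    """Mine substrings present in positives and absent from all negatives.

    Returns up to ``top_k`` motifs ranked by positive coverage
    (descending), ties broken by length (ascending) then lexicographic
    order.  If positives and negatives share all substrings the result
    is empty.
    """
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both positive and negative datasets must be non-empty")
    neg_subs: set[str] = set()
    for rec in neg:
        neg_subs |= _substrings(rec.sequence, min_len, max_len)
    coverage: dict[str, int] = {}
    for rec in pos:
        for sub in _substrings(rec.sequence, min_len, max_len):
            if sub not in neg_subs:
                coverage[sub] = coverage.get(sub, 0) + 1
    ranked = sorted(coverage, key=lambda m: (-coverage[m], len(m), m))[:top_k]
    return MotifSet(ranked, {m: coverage[m] for m in ranked})


def encode_motifs(seq: str, ms: MotifSet) -> pd.Series:
    """Binary presence flags for each motif (monotone under concatenation)."""
    values = [1.0 if m in seq else 0.0 for m in ms.motifs]
    return pd.Series(values, index=ms.feature_names(), dtype=float)
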