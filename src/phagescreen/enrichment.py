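"""Variant counting, ranking and per-selection summary statistics.

Counts QC-passed variable-region peptides into a deterministic ranked table,
computes the headline per-selection numbers (top frequency, number of
sequences above a read-count threshold), naive-library quality statistics,
and cross-selection overlap (Venn region) counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantTable",
    "SelectionSummary",
    "count_variants",
    "selection_summary",
    "top_n",
    "overlap_analysis",
    "library_qc",
]


@dataclass(frozen=True)
class VariantTable:
    """Ranked unique peptides with read counts and frequencies.

    Rows are sorted by read count descending, ties broken lexicographically by
    peptide, so that ranking is reproducible.  Frequencies are computed over
    the retained (QC-passed) reads.
    """

    selection_id: str
    peptides: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.peptides) != len(self.counts):
            raise ValueError("peptides and counts length mismatch")
        if any(c < 1 for c in self.counts):
            raise ValueError("all counts must be >= 1")
        order = sorted(
            range(len(self.peptides)),
            key=lambda i: (-self.counts[i], self.peptides[i]),
        )
        object.__setattr__(
            self, "peptides", tuple(self.peptides[i] for i in order)
        )
        object.__setattr__(self, "counts", tuple(self.counts[i] for i in order))

    @property
    def total_retained_reads(self) -> int:
        return sum(self.counts)

    @property
    def frequencies(self) -> np.ndarray:
        total = self.total_retained_reads
        return np.asarray(self.counts, dtype=float) / total if total else np.array([])

    @property
    def is_empty(self) -> bool:
        return len(self.peptides) == 0

    def __len__(self) -> int:
        return len(self.peptides)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peptide": self.peptides,
                "read_count": self.counts,
                "frequency": self.frequencies,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, selection_id: str = "") -> "VariantTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            selection_id=selection_id or Path(path).stem,
            peptides=tuple(df["peptide"].astype(str)),
            counts=tuple(int(c) for c in df["read_count"]),
        )


@dataclass(frozen=True)
class SelectionSummary:
    """Headline numbers for one selection round."""

    top_freq_percent: float
    n_seq_min_reads: int
    threshold: int

    def to_dict(self) -> dict:
        return {
            "top_freq_percent": self.top_freq_percent,
            "n_seq_min_reads": self.n_seq_min_reads,
            "threshold": self.threshold,
        }


def count_variants(
    peptides: Iterable[str], selection_id: str = ""
) -> VariantTable:
    """Exact multiset count of peptides into a ranked :class:`VariantTable`."""
    counter = Counter(peptides)
    return VariantTable(
        selection_id=selection_id,
        peptides=tuple(counter.keys()),
        counts=tuple(counter.values()),
    )


def selection_summary(table: VariantTable, min_reads: int = 100) -> SelectionSummary:
    """Top frequency (percent) and count of peptides with >= ``min_reads`` reads."""
    if table.is_empty:
        raise ValueError("cannot summarize an empty variant table")
    top_freq = 100.0 * table.counts[0] / table.total_retained_reads
    n_seq = sum(1 for c in table.counts if c >= min_reads)
    return SelectionSummary(
        top_freq_percent=top_freq, n_seq_min_reads=n_seq, threshold=min_reads
    )


def top_n(table: VariantTable, n: int = 500) -> list[str]:
    """First ``min(n, len(table))`` peptides under the deterministic ranking."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return list(table.peptides[:n])


def overlap_analysis(
    sets: Sequence[tuple[str, Iterable[str]]],
) -> dict[frozenset[str], int]:
    """Counts of every exclusive Venn region over 2-4 peptide sets.

    Returns a mapping from the frozenset of selection ids defining a region
    (peptides in exactly those sets) to the number of peptides in it.  Region
    counts sum to the size of the union.
    """
    if not 2 <= len(sets) <= 4:
        raise ValueError("overlap_analysis supports 2 to 4 sets")
    ids = [sid for sid, _ in sets]
    if len(set(ids)) != len(ids):
        raise ValueError("selection ids must be unique")
    members = {sid: set(peps) for sid, peps in sets}
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(ids) + 1):
        for combo in combinations(ids, r):
            regions[frozenset(combo)] = 0
    union = set().union(*members.values())
    for pep in union:
        containing = frozenset(sid for sid in ids if pep in members[sid])
        regions[containing] += 1
    return regions


def library_qc(
    table: VariantTable, alphabet: Iterable[str] | None = None
) -> tuple[float, float, pd.DataFrame]:
    """Naive-library statistics from a variant table.

    Returns ``(unique_read_fraction, fraction_reads_seen_at_most_twice,
    position_frequency_matrix)``.  The fractions are over reads: a read is
    "unique" when its peptide was observed exactly once.  The matrix has one
    row per variable position and one column per alphabet letter; entries are
    read-weighted letter frequencies and each row sums to 1.
    """
    if table.is_empty:
        raise ValueError("empty variant table")
    lengths = {len(p) for p in table.peptides}
    if len(lengths) != 1:
        raise ValueError(f"mixed peptide lengths: {sorted(lengths)}")
    length = lengths.pop()
    counts = np.asarray(table.counts)
    total = counts.sum()
    unique_fraction = counts[counts == 1].sum() / total
    le2_fraction = counts[counts <= 2].sum() / total

    letters = sorted(
        set(alphabet) if alphabet is not None else {a for p in table.peptides for a in p}
    )
    idx = {a: j for j, a in enumerate(letters)}
    mat = np.zeros((length, len(letters)))
    for pep, c in zip(table.peptides, table.counts):
        for pos, aa in enumerate(pep):
            if aa not in idx:
                raise ValueError(f"letter {aa!r} not in alphabet")
            mat[pos, idx[aa]] += c
    mat /= mat.sum(axis=1, keepdims=True)
    freq = pd.DataFrame(mat, index=range(length), columns=letters)
    return float(unique_fraction), float(le2_fraction), freq
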