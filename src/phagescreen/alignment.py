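"""Ungapped peptide similarity scoring, cutoff clustering and logo matrices.

Equal-length peptides are compared position by position with an integer
similarity matrix whose scores run from 0 (no resemblance) to 9 (identity).
Clusters are seed-centric: all peptides scoring at least a cutoff against a
chosen seed.  Logo matrices report per-position letter frequencies and their
information content in bits.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .enrichment import VariantTable

__all__ = [
    "SimilarityMatrix",
    "ClusterResult",
    "LogoMatrices",
    "default_matrix",
    "pairwise_score",
    "all_vs_all",
    "cluster_by_cutoff",
    "logo",
]

# Physicochemical groups used to build the default matrix (no cysteine).
_GROUPS = {
    "aliphatic": "ILVM",
    "aromatic": "FWY",
    "polar": "STNQ",
    "positive": "KRH",
    "negative": "DE",
    "small": "AG",
    "proline": "P",
}
_RELATED = [
    ("aromatic", "aliphatic"),
    ("polar", "positive"),
    ("polar", "negative"),
]
IDENTITY_SCORE = 9
SAME_GROUP_SCORE = 6
RELATED_GROUP_SCORE = 3


class SimilarityMatrix:
    """Symmetric integer amino-acid similarity matrix with scores in [0, 9]."""

    def __init__(self, scores: pd.DataFrame):
        if list(scores.index) != list(scores.columns):
            raise ValueError("matrix index and columns must agree")
        vals = scores.to_numpy()
        if not np.array_equal(vals, vals.T):
            raise ValueError("matrix must be symmetric")
        if vals.min() < 0 or vals.max() > 9:
            raise ValueError("scores must lie in [0, 9]")
        self._df = scores.astype(int)
        self.alphabet: tuple[str, ...] = tuple(scores.index)
        self._idx = {a: i for i, a in enumerate(self.alphabet)}
        self._arr = self._df.to_numpy()

    def __getitem__(self, pair: tuple[str, str]) -> int:
        a, b = pair
        try:
            return int(self._arr[self._idx[a], self._idx[b]])
        except KeyError as exc:
            raise KeyError(f"letter {exc.args[0]!r} not in matrix alphabet") from None

    def to_dataframe(self) -> pd.DataFrame:
        return self._df.copy()

    def to_tsv(self, path: str | Path) -> None:
        self._df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = [str(c) for c in df.columns]
        df.index = [str(i) for i in df.index]
        return cls(df)

    @property
    def checksum(self) -> str:
        """MD5 of the canonical TSV serialization, recorded with cluster output."""
        buf = io.StringIO()
        self._df.sort_index().sort_index(axis=1).to_csv(buf, sep="\t")
        return hashlib.md5(buf.getvalue().encode()).hexdigest()


def default_matrix(alphabet: Optional[Iterable[str]] = None) -> SimilarityMatrix:
    """Group-structured default matrix: identity 9, same group 6, related
    groups 3, otherwise 0."""
    letters = sorted(alphabet) if alphabet else sorted("".join(_GROUPS.values()))
    group_of = {a: g for g, members in _GROUPS.items() for a in members}
    related = {frozenset(pair) for pair in _RELATED}
    n = len(letters)
    arr = np.zeros((n, n), dtype=int)
    for i, a in enumerate(letters):
        for j, b in enumerate(letters):
            ga, gb = group_of.get(a), group_of.get(b)
            if a == b:
                arr[i, j] = IDENTITY_SCORE
            elif ga is not None and ga == gb:
                arr[i, j] = SAME_GROUP_SCORE
            elif ga and gb and frozenset((ga, gb)) in related:
                arr[i, j] = RELATED_GROUP_SCORE
    return SimilarityMatrix(pd.DataFrame(arr, index=letters, columns=letters))


def pairwise_score(a: str, b: str, m: SimilarityMatrix) -> int:
    """Ungapped position-wise score: sum of m[a_i, b_i] over positions."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(m[x, y] for x, y in zip(a, b))


def all_vs_all(
    peptides: Sequence[str], m: SimilarityMatrix
) -> list[tuple[int, int, int]]:
    """All n(n-1)/2 pairwise scores as (i, j, score) with i < j."""
    lengths = {len(p) for p in peptides}
    if len(lengths) > 1:
        raise ValueError(f"peptides must share one length, got {sorted(lengths)}")
    out = []
    for i in range(len(peptides)):
        for j in range(i + 1, len(peptides)):
            try:
                s = pairwise_score(peptides[i], peptides[j], m)
            except (KeyError, ValueError) as exc:
                raise ValueError(f"pair ({i}, {j}): {exc}") from exc
            out.append((i, j, s))
    return out


@dataclass(frozen=True)
class ClusterResult:
    """Star cluster of peptides scoring >= cutoff against a seed."""

    seed: str
    members: tuple[tuple[str, int, int], ...]  # (peptide, score, read_count)
    cutoff: int
    matrix_checksum: str = ""

    def peptide_list(self) -> list[str]:
        return [p for p, _, _ in self.members]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.members, columns=["peptide", "score", "read_count"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def cluster_by_cutoff(
    seed: str,
    table: VariantTable | Sequence[tuple[str, int]],
    m: SimilarityMatrix,
    cutoff: int,
) -> ClusterResult:
    """All peptides with pairwise score vs. ``seed`` at or above ``cutoff``.

    Members are sorted by score descending, then read count descending, then
    peptide.  The seed itself is included whenever present in the input (its
    self-score is maximal by construction of the matrix diagonal).
    """
    if isinstance(table, VariantTable):
        entries = list(zip(table.peptides, table.counts))
    else:
        entries = list(table)
    if not 0 <= cutoff <= IDENTITY_SCORE * len(seed):
        raise ValueError(f"cutoff must be in [0, {IDENTITY_SCORE * len(seed)}]")
    members = []
    for pep, count in entries:
        if len(pep) != len(seed):
            raise ValueError(f"peptide {pep!r} length != seed length")
        s = pairwise_score(seed, pep, m)
        if s >= cutoff:
            members.append((pep, s, int(count)))
    members.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return ClusterResult(
        seed=seed, members=tuple(members), cutoff=cutoff,
        matrix_checksum=m.checksum,
    )


@dataclass(frozen=True)
class LogoMatrices:
    """Per-position letter frequencies and information-scaled (bits) heights."""

    frequency: pd.DataFrame  # positions x alphabet, rows sum to 1
    bits: pd.DataFrame       # frequency * per-position information content
    alphabet_size: int

    @property
    def max_bits(self) -> float:
        return float(np.log2(self.alphabet_size))

    def information_per_position(self) -> np.ndarray:
        return self.bits.to_numpy().sum(axis=1)


def logo(
    members: Sequence[tuple[str, float]],
    alphabet_size: int = 19,
    alphabet: Optional[Iterable[str]] = None,
) -> LogoMatrices:
    """Weighted frequency and bits logo matrices for equal-length peptides.

    The information content of a position is ``log2(alphabet_size) - H`` with
    H the Shannon entropy (base 2) of the weighted letter frequencies; each
    letter's bits entry is its frequency times that information content.
    """
    if not members:
        raise ValueError("no sequences given")
    lengths = {len(p) for p, _ in members}
    if len(lengths) != 1:
        raise ValueError("sequences must share one length")
    length = lengths.pop()
    if any(w < 0 for _, w in members):
        raise ValueError("weights must be >= 0")
    total = sum(w for _, w in members)
    if total <= 0:
        raise ValueError("total weight must be positive")

    letters = sorted(
        set(alphabet) if alphabet is not None else {a for p, _ in members for a in p}
    )
    idx = {a: j for j, a in enumerate(letters)}
    freq = np.zeros((length, len(letters)))
    for pep, w in members:
        for pos, aa in enumerate(pep):
            if aa not in idx:
                raise ValueError(f"letter {aa!r} not in alphabet")
            freq[pos, idx[aa]] += w
    freq /= total

    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    entropy = -plogp.sum(axis=1)
    info = np.maximum(np.log2(alphabet_size) - entropy, 0.0)
    bits = freq * info[:, None]

    positions = list(range(length))
    return LogoMatrices(
        frequency=pd.DataFrame(freq, index=positions, columns=letters),
        bits=pd.DataFrame(bits, index=positions, columns=letters),
        alphabet_size=alphabet_size,
    )
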