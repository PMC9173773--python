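"""FASTQ read quality control and variable-region translation.

Filter cascade for amplicon reads of a scaffold library: undetermined bases
and low Phred scores are rejected first, then reads are oriented to the sense
strand via the template's DNA flank markers, scanned for in-frame stop codons
(TAA/TGA; TAG reads through as Gln), checked against the expected flank or
constant-region nucleotides, and finally translated into variable-region
peptides.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

from .library_design import (
    CodonDesign,
    ScaffoldTemplate,
    construct_dna,
    reverse_complement,
    variable_codon_spans,
)

__all__ = [
    "Fate",
    "ReadRecord",
    "QCConfig",
    "QCReport",
    "orient_read",
    "quality_filter",
    "frame_and_constant_check",
    "translate_variable_region",
    "run_qc",
    "iter_fastq",
    "TranslationError",
]

# Standard genetic code with the amber codon reassigned to glutamine
# (suppressor-strain read-through); TAA and TGA remain stops.
_CODON_TO_AA: dict[str, str] = dict(
    CodonTable.unambiguous_dna_by_id[1].forward_table
)
_CODON_TO_AA["TAG"] = "Q"
_HARD_STOPS = frozenset({"TAA", "TGA"})


class Fate(str, Enum):
    PASSED = "passed"
    CONTAINS_N = "contains_N"
    LOW_QUALITY = "low_quality"
    IN_FRAME_STOP = "in_frame_stop"
    FLANK_MISMATCH = "flank_mismatch"
    CONSTANT_MISMATCH = "constant_mismatch"
    UNORIENTED = "unoriented"
    FRAME_ERROR = "frame_error"


FAIL_FATES = tuple(f for f in Fate if f is not Fate.PASSED)


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with bases, per-base Phred scores and QC state."""

    read_id: str
    bases: str
    quals: tuple[int, ...]
    orientation: str = "undetermined"  # sense | antisense | undetermined
    fate: Optional[Fate] = None

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals must have equal length")

    @property
    def passed(self) -> bool:
        return self.fate is Fate.PASSED


@dataclass(frozen=True)
class QCConfig:
    min_phred: int = 21
    max_flank_mismatch: int = 0
    codon_design: CodonDesign = field(default_factory=CodonDesign)

    def __post_init__(self) -> None:
        if self.min_phred < 0:
            raise ValueError("min_phred must be >= 0")
        if self.max_flank_mismatch < 0:
            raise ValueError("max_flank_mismatch must be >= 0")


@dataclass
class QCReport:
    """Counts per QC fate for one FASTQ file."""

    counts: dict[str, int] = field(
        default_factory=lambda: {f.value: 0 for f in Fate}
    )

    def record(self, fate: Fate) -> None:
        self.counts[fate.value] += 1

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def retained(self) -> int:
        return self.counts[Fate.PASSED.value]

    @property
    def retention_fraction(self) -> float:
        return self.retained / self.total if self.total else 0.0

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "retained": self.retained,
            "retention_fraction": self.retention_fraction,
            "fates": dict(self.counts),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def orient_read(read: ReadRecord, template: ScaffoldTemplate) -> ReadRecord:
    """Convert a read to the sense direction using the 5' flank marker.

    A read whose bases contain the flank on the given strand is sense; one
    whose reverse complement contains it is antisense and is flipped in
    silico.  A read matching neither or both strands gets fate=unoriented.
    """
    marker = template.dna_flank_5p
    if not marker:
        raise ValueError("template has no 5' DNA flank marker")
    fwd = marker in read.bases
    rc = reverse_complement(read.bases)
    rev = marker in rc
    if fwd and not rev:
        return replace(read, orientation="sense")
    if rev and not fwd:
        return replace(
            read,
            bases=rc,
            quals=tuple(reversed(read.quals)),
            orientation="antisense",
        )
    return replace(read, fate=Fate.UNORIENTED)


def quality_filter(read: ReadRecord, min_phred: int = 21) -> Fate:
    """Reject reads with any N base, then any Phred score below ``min_phred``."""
    if min_phred < 0:
        raise ValueError("min_phred must be >= 0")
    if "N" in read.bases:
        return Fate.CONTAINS_N
    if any(q < min_phred for q in read.quals):
        return Fate.LOW_QUALITY
    return Fate.PASSED


def _flank5_construct_pos(template: ScaffoldTemplate) -> int:
    """Nucleotide offset of the 5' flank within the construct DNA."""
    first = template.randomized_positions[0]
    return 3 * first - len(template.dna_flank_5p)


def _flank5_occurrences(bases: str, f5: str) -> list[int]:
    out, i = [], bases.find(f5)
    while i >= 0:
        out.append(i)
        i = bases.find(f5, i + 1)
    return out


def in_frame_stop_check(read: ReadRecord, template: ScaffoldTemplate) -> Fate:
    """Scan every full codon of the read, in the frame anchored on the 5'
    flank, for a hard stop (TAA/TGA)."""
    i = read.bases.find(template.dna_flank_5p)
    if i < 0:
        return Fate.PASSED  # frame undefined; flank check will reject
    offset = i - _flank5_construct_pos(template)
    start = offset % 3
    for k in range(start, len(read.bases) - 2, 3):
        if read.bases[k : k + 3] in _HARD_STOPS:
            return Fate.IN_FRAME_STOP
    return Fate.PASSED


def frame_and_constant_check(
    read: ReadRecord,
    template: ScaffoldTemplate,
    config: Optional[QCConfig] = None,
) -> tuple[Fate, Optional[str]]:
    """Check flank / constant-region nucleotides and extract variable codons.

    Templates with one contiguous variable block ("loop" style) require both
    DNA flanks to match exactly and to bracket exactly ``3 * n_randomized``
    nucleotides; everything between is returned as the variable codon string.
    Templates with interleaved variable positions ("side" style) compare every
    constant-region nucleotide of the read against the expected construct DNA
    (variable codons excepted) over the read/construct overlap.

    The variable region itself can recreate a flank motif by chance, so every
    occurrence of the 5' flank is tried and the first consistent anchoring
    (matching 3' flank, or full constant-region coverage) is used.
    """
    config = config or QCConfig()
    f5 = template.dna_flank_5p
    hits = _flank5_occurrences(read.bases, f5)
    if not hits:
        return Fate.FLANK_MISMATCH, None
    var_nt = 3 * template.n_randomized
    if template.is_contiguous:
        f3 = template.dna_flank_3p
        for i in hits:
            j = i + len(f5) + var_nt
            if j + len(f3) > len(read.bases):
                continue
            observed_f3 = read.bases[j : j + len(f3)]
            if sum(a != b for a, b in zip(observed_f3, f3)) <= config.max_flank_mismatch:
                return Fate.PASSED, read.bases[i + len(f5) : j]
        return Fate.FLANK_MISMATCH, None
    # interleaved: compare against the full expected construct
    expected = construct_dna(template, config.codon_design)
    pos5 = _flank5_construct_pos(template)
    spans = variable_codon_spans(template)
    last_var_nt = spans[-1][1]
    is_var = np.zeros(len(expected), dtype=bool)
    for a, b in spans:
        is_var[a:b] = True
    anchored = False
    for i in hits:
        offset = i - pos5
        if offset < 0 or offset + last_var_nt > len(read.bases):
            continue
        anchored = True
        stop = min(len(expected), len(read.bases) - offset)
        if all(
            is_var[c] or read.bases[offset + c] == expected[c]
            for c in range(stop)
        ):
            codons = "".join(
                read.bases[offset + a : offset + b] for a, b in spans
            )
            return Fate.PASSED, codons
    return (Fate.CONSTANT_MISMATCH if anchored else Fate.FLANK_MISMATCH), None


class TranslationError(ValueError):
    def __init__(self, fate: Fate, message: str):
        self.fate = fate
        super().__init__(message)


def translate_variable_region(codons: str) -> str:
    """Translate variable-region codons; TAG reads as Q, TAA/TGA are fatal.

    Raises :class:`TranslationError` with fate ``frame_error`` for a length
    not divisible by 3 and ``in_frame_stop`` for a hard stop codon.
    """
    if len(codons) % 3 != 0:
        raise TranslationError(
            Fate.FRAME_ERROR, f"codon string length {len(codons)} not divisible by 3"
        )
    peptide = []
    for k in range(0, len(codons), 3):
        codon = codons[k : k + 3]
        if codon in _HARD_STOPS:
            raise TranslationError(Fate.IN_FRAME_STOP, f"stop codon {codon}")
        try:
            peptide.append(_CODON_TO_AA[codon])
        except KeyError:
            raise TranslationError(
                Fate.FRAME_ERROR, f"unrecognized codon {codon!r}"
            ) from None
    return "".join(peptide)


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, "rt")
    return open(p, "rt")


def iter_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a (optionally gzipped) Phred+33 FASTQ file."""
    with _open_maybe_gzip(path) as handle:
        for idx, rec in enumerate(SeqIO.parse(handle, "fastq")):
            try:
                yield ReadRecord(
                    read_id=rec.id,
                    bases=str(rec.seq).upper(),
                    quals=tuple(rec.letter_annotations["phred_quality"]),
                )
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record {idx}: {exc}") from exc


def qc_read(
    read: ReadRecord, template: ScaffoldTemplate, config: Optional[QCConfig] = None
) -> tuple[ReadRecord, Optional[str]]:
    """Run the full per-read cascade; returns the fated read and its peptide.

    Order: N / quality first, then in-frame stop (these remove the vast
    majority of bad reads), then orientation and flank/constant checks, then
    translation.
    """
    config = config or QCConfig()
    fate = quality_filter(read, config.min_phred)
    if fate is not Fate.PASSED:
        return replace(read, fate=fate), None
    oriented = orient_read(read, template)
    if oriented.fate is Fate.UNORIENTED:
        return oriented, None
    fate = in_frame_stop_check(oriented, template)
    if fate is not Fate.PASSED:
        return replace(oriented, fate=fate), None
    fate, codons = frame_and_constant_check(oriented, template, config)
    if fate is not Fate.PASSED:
        return replace(oriented, fate=fate), None
    try:
        peptide = translate_variable_region(codons)
    except TranslationError as exc:
        return replace(oriented, fate=exc.fate), None
    return replace(oriented, fate=Fate.PASSED), peptide


def run_qc(
    fastq_path: str | Path,
    template: ScaffoldTemplate,
    config: Optional[QCConfig] = None,
) -> tuple[list[tuple[str, str]], QCReport]:
    """QC a whole FASTQ file.

    Returns ``(passed, report)`` where ``passed`` is a list of
    ``(read_id, peptide)`` in input order and ``report`` counts every fate.
    """
    config = config or QCConfig()
    report = QCReport()
    passed: list[tuple[str, str]] = []
    for read in iter_fastq(fastq_path):
        fated, peptide = qc_read(read, template, config)
        report.record(fated.fate)
        if peptide is not None:
            passed.append((fated.read_id, peptide))
    return passed, report
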