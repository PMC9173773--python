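"""Synthetic panning simulator.

Generates FASTQ datasets with the statistical structure the analysis expects:
naive libraries sampled uniformly over the template alphabet, multi-round
affinity-weighted selection that enriches motif families into few-percent top
frequencies, per-base sequencing errors with degraded quality scores, and
random read orientation.  All randomness flows from a single seed.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .library_design import (
    CodonDesign,
    ScaffoldTemplate,
    construct_dna,
    reverse_complement,
)
from .read_qc import ReadRecord

__all__ = [
    "MotifFamily",
    "BinderModel",
    "SimulationConfig",
    "sample_naive_pool",
    "simulate_naive_library",
    "simulate_selection",
    "add_sequencing_errors",
    "pool_to_reads",
    "write_fastq",
    "ground_truth_table",
]

_QUAL_MIN, _QUAL_MAX = 2, 41
#: Correct bases never drop below this score, so an error-free simulation
#: passes the default Phred >= 21 filter in full.
_GOOD_QUAL_FLOOR = 22
#: Substituted / N-masked bases get this lower quality profile; its upper
#: tail lets a fraction of errors slip past the quality filter.
_ERROR_QUAL_MEAN, _ERROR_QUAL_SD = 15.0, 6.0


@dataclass(frozen=True)
class MotifFamily:
    """One motif: a per-position letter score table plus a family weight."""

    position_scores: tuple[Mapping[str, float], ...]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("family weight must be >= 0")
        for tbl in self.position_scores:
            if any(v < 0 for v in tbl.values()):
                raise ValueError("motif scores must be >= 0")

    @classmethod
    def from_consensus(cls, consensus: str, match_score: float = 1.0,
                       weight: float = 1.0) -> "MotifFamily":
        return cls(
            position_scores=tuple({aa: match_score} for aa in consensus),
            weight=weight,
        )

    def score(self, peptide: str) -> float:
        if len(peptide) != len(self.position_scores):
            raise ValueError("peptide length does not match motif")
        return sum(
            tbl.get(aa, 0.0) for tbl, aa in zip(self.position_scores, peptide)
        )

    def sample(self, rng: np.random.Generator, alphabet: Sequence[str]) -> str:
        """Draw one family member: per position, letters weighted by score
        (uniform over the alphabet where the score table is empty)."""
        letters = sorted(alphabet)
        out = []
        for tbl in self.position_scores:
            if tbl:
                keys = sorted(tbl)
                w = np.array([tbl[k] for k in keys], dtype=float)
                out.append(keys[int(rng.choice(len(keys), p=w / w.sum()))])
            else:
                out.append(letters[int(rng.integers(len(letters)))])
        return "".join(out)


@dataclass(frozen=True)
class BinderModel:
    """Motif families plus a background fitness for non-binders."""

    families: tuple[MotifFamily, ...]
    background: float = 0.0

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("at least one motif family required")
        if self.background < 0:
            raise ValueError("background fitness must be >= 0")

    def fitness(self, peptide: str) -> float:
        return self.background + max(
            f.weight * f.score(peptide) for f in self.families
        )


@dataclass(frozen=True)
class SimulationConfig:
    n_reads: int = 10_000
    n_rounds: int = 3
    error_rate: float = 0.0
    n_rate: float = 0.0
    antisense_fraction: float = 0.0
    qual_mean: float = 35.0
    qual_sd: float = 4.0
    stringency: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("error_rate", "n_rate", "antisense_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.error_rate > 0.2:
            raise ValueError("error_rate above 0.2 is not supported")
        if self.n_reads < 0 or self.n_rounds < 0:
            raise ValueError("n_reads and n_rounds must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def sample_naive_pool(
    template: ScaffoldTemplate, n: int, rng: np.random.Generator
) -> Counter:
    """Multiset of ``n`` peptides drawn uniformly over alphabet^k."""
    letters = np.array(sorted(template.alphabet))
    draws = rng.integers(len(letters), size=(n, template.n_randomized))
    return Counter("".join(letters[row]) for row in draws)


def _simulate_quals(n: int, rng: np.random.Generator, mean: float, sd: float,
                    floor: int = _GOOD_QUAL_FLOOR) -> np.ndarray:
    q = np.rint(rng.normal(mean, sd, size=n))
    return np.clip(q, floor, _QUAL_MAX).astype(int)


def add_sequencing_errors(
    reads: Sequence[ReadRecord],
    error_rate: float,
    rng: np.random.Generator,
    n_rate: float = 0.0,
    qual_sd: float = 4.0,
) -> list[ReadRecord]:
    """Per-base substitution (and optional N masking) with degraded quality.

    Each base is substituted with probability ``error_rate`` (uniform over the
    three other bases) and replaced by N with probability ``n_rate``; mutated
    bases are reassigned a lower-mean simulated quality.
    """
    if not 0.0 <= error_rate <= 0.2:
        raise ValueError("error_rate must be in [0, 0.2]")
    others = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
    out = []
    for read in reads:
        bases = list(read.bases)
        quals = np.asarray(read.quals)
        n = len(bases)
        hit = rng.random(n) < error_rate
        n_hit = rng.random(n) < n_rate
        if hit.any() or n_hit.any():
            quals = quals.copy()
            for i in np.nonzero(hit)[0]:
                bases[i] = others[bases[i]][int(rng.integers(3))]
            for i in np.nonzero(hit | n_hit)[0]:
                quals[i] = _simulate_quals(
                    1, rng, _ERROR_QUAL_MEAN, _ERROR_QUAL_SD, floor=_QUAL_MIN
                )[0]
            for i in np.nonzero(n_hit)[0]:
                bases[i] = "N"
        out.append(
            ReadRecord(read.read_id, "".join(bases), tuple(int(q) for q in quals))
        )
    return out


def pool_to_reads(
    pool: Counter | Sequence[str],
    template: ScaffoldTemplate,
    design: CodonDesign,
    config: SimulationConfig,
    rng: np.random.Generator,
    id_prefix: str = "read",
) -> list[ReadRecord]:
    """Render a peptide multiset as amplicon reads with qualities, errors and
    mixed orientation."""
    peptides = (
        list(pool.elements()) if isinstance(pool, Counter) else list(pool)
    )
    reads = []
    for k, pep in enumerate(peptides):
        dna = construct_dna(template, design, pep, rng=rng)
        quals = _simulate_quals(len(dna), rng, config.qual_mean, config.qual_sd)
        reads.append(
            ReadRecord(f"{id_prefix}_{k}", dna, tuple(int(q) for q in quals))
        )
    if config.error_rate > 0 or config.n_rate > 0:
        reads = add_sequencing_errors(
            reads, config.error_rate, rng, n_rate=config.n_rate,
            qual_sd=config.qual_sd,
        )
    if config.antisense_fraction > 0:
        flipped = []
        for read in reads:
            if rng.random() < config.antisense_fraction:
                read = ReadRecord(
                    read.read_id,
                    reverse_complement(read.bases),
                    tuple(reversed(read.quals)),
                )
            flipped.append(read)
        reads = flipped
    return reads


def write_fastq(reads: Sequence[ReadRecord], path: str | Path) -> Path:
    """Write Phred+33 FASTQ; gzipped when the path ends in ``.gz``."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for read in reads:
            qual_str = "".join(chr(q + 33) for q in read.quals)
            fh.write(f"@{read.read_id}\n{read.bases}\n+\n{qual_str}\n")
    return path


def simulate_naive_library(
    template: ScaffoldTemplate,
    n_reads: int,
    codon_design: Optional[CodonDesign] = None,
    config: Optional[SimulationConfig] = None,
    out_path: Optional[str | Path] = None,
) -> tuple[list[ReadRecord], list[str]]:
    """Uniform naive-library FASTQ plus the planted ground-truth peptides.

    Returns ``(reads, peptides)`` in matching order; also writes the FASTQ
    when ``out_path`` is given.
    """
    design = codon_design or CodonDesign()
    config = config or SimulationConfig(n_reads=n_reads)
    rng = config.rng()
    letters = np.array(sorted(template.alphabet))
    draws = rng.integers(len(letters), size=(n_reads, template.n_randomized))
    peptides = ["".join(letters[row]) for row in draws]
    reads = pool_to_reads(peptides, template, design, config, rng, id_prefix="naive")
    if out_path is not None:
        write_fastq(reads, out_path)
    return reads, peptides


def selection_weights(
    pool: Counter, model: BinderModel, stringency: float
) -> pd.Series:
    """Unnormalized survival weights: count * exp(stringency * fitness)."""
    peptides = sorted(pool)
    fitness = np.array([model.fitness(p) for p in peptides])
    counts = np.array([pool[p] for p in peptides], dtype=float)
    w = counts * np.exp(stringency * fitness)
    return pd.Series(w, index=peptides)


def simulate_selection(
    pool: Counter,
    model: BinderModel,
    n_rounds: int,
    config: SimulationConfig,
    template: Optional[ScaffoldTemplate] = None,
    codon_design: Optional[CodonDesign] = None,
    out_dir: Optional[str | Path] = None,
) -> list[Counter]:
    """Multi-round affinity-weighted selection by multinomial resampling.

    Returns pools indexed by round: element 0 is (a copy of) the input pool,
    element r the eluate after round r.  When ``out_dir`` and ``template`` are
    given, a FASTQ is written per selection round (``round_1.fastq`` ...).
    """
    if not pool:
        raise ValueError("input pool is empty")
    rng = config.rng()
    pools = [Counter(pool)]
    for r in range(1, n_rounds + 1):
        current = pools[-1]
        weights = selection_weights(current, model, config.stringency)
        total = weights.to_numpy().sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("degenerate selection weights (all zero)")
        probs = weights.to_numpy() / total
        counts = rng.multinomial(config.n_reads, probs)
        nxt = Counter(
            {p: int(c) for p, c in zip(weights.index, counts) if c > 0}
        )
        pools.append(nxt)
    if out_dir is not None:
        if template is None:
            raise ValueError("template required to write FASTQ output")
        design = codon_design or CodonDesign()
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for r, round_pool in enumerate(pools[1:], start=1):
            reads = pool_to_reads(
                round_pool, template, design, config, rng,
                id_prefix=f"r{r}",
            )
            write_fastq(reads, out_dir / f"round_{r}.fastq")
    return pools


def ground_truth_table(pool: Counter, model: BinderModel) -> pd.DataFrame:
    """Per-peptide true fitness table for test assertions (TSV-friendly)."""
    peptides = sorted(pool)
    return pd.DataFrame(
        {
            "peptide": peptides,
            "count": [pool[p] for p in peptides],
            "fitness": [model.fitness(p) for p in peptides],
        }
    )
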