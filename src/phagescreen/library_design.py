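"""Scaffold library definitions.

A scaffold library is a constant protein context with a small number of
randomized surface or loop positions.  This module defines the template and
codon-design data structures, computes theoretical diversity, rebuilds full
variant proteins from variable-region peptides, and locates PCR amplicons in
construct DNA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "STANDARD_AA",
    "DEFAULT_ALPHABET",
    "CodonDesign",
    "ScaffoldTemplate",
    "PrimerSiteError",
    "builtin_template",
    "load_template",
    "theoretical_diversity",
    "build_variant_protein",
    "extract_variable_region",
    "construct_dna",
    "variable_codon_spans",
    "find_amplicon",
    "reverse_complement",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: 19 standard residues; cysteine excluded (solvent-exposed Cys promotes
#: dimerization and is a selection liability).
DEFAULT_ALPHABET = frozenset(STANDARD_AA) - {"C"}

PLACEHOLDER = "X"

# One common E. coli codon per amino acid.  No cysteine codon; TAA/TGA never
# appear; TAG is carried as an extra glutamine codon (amber suppression).
_DEFAULT_CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCG",),
    "D": ("GAT",),
    "E": ("GAA",),
    "F": ("TTT",),
    "G": ("GGT",),
    "H": ("CAT",),
    "I": ("ATT",),
    "K": ("AAA",),
    "L": ("CTG",),
    "M": ("ATG",),
    "N": ("AAC",),
    "P": ("CCG",),
    "Q": ("CAG", "TAG"),
    "R": ("CGT",),
    "S": ("AGC",),
    "T": ("ACC",),
    "V": ("GTG",),
    "W": ("TGG",),
    "Y": ("TAT",),
}


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


@dataclass(frozen=True)
class CodonDesign:
    """Permitted codons per amino acid, with stop codons restricted.

    Invariants: no cysteine codon; TAA and TGA are absent everywhere; TAG, if
    present, is a glutamine codon.
    """

    codons: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_CODONS)
    )

    def __post_init__(self) -> None:
        if "C" in self.codons:
            raise ValueError("codon design must not encode cysteine")
        for aa, cods in self.codons.items():
            for c in cods:
                if c in ("TAA", "TGA"):
                    raise ValueError(f"forbidden stop codon {c} for {aa}")
                if c == "TAG" and aa != "Q":
                    raise ValueError("TAG may only encode Q")
                if len(c) != 3 or any(b not in "ACGT" for b in c):
                    raise ValueError(f"malformed codon {c!r}")

    def codon_for(self, aa: str) -> str:
        """Deterministic (first-listed) codon for one residue."""
        try:
            return self.codons[aa][0]
        except KeyError:
            raise KeyError(f"no codon defined for residue {aa!r}") from None

    def reverse_translate(
        self, peptide: str, rng: Optional[np.random.Generator] = None
    ) -> str:
        """DNA for a peptide; uniform over permitted codons when an rng is given."""
        out = []
        for aa in peptide:
            cods = self.codons.get(aa)
            if not cods:
                raise KeyError(f"no codon defined for residue {aa!r}")
            if rng is None or len(cods) == 1:
                out.append(cods[0])
            else:
                out.append(cods[int(rng.integers(len(cods)))])
        return "".join(out)


@dataclass(frozen=True)
class ScaffoldTemplate:
    """A library definition: constant context plus randomized positions.

    ``constant_sequence`` holds the full displayed protein with ``placeholder``
    at every randomized position.  DNA flanks bracket the variable-region
    codons and are used for read orientation and flank checks.
    """

    name: str
    constant_sequence: str
    dna_flank_5p: str = ""
    dna_flank_3p: str = ""
    placeholder: str = PLACEHOLDER
    alphabet: frozenset[str] = DEFAULT_ALPHABET
    randomized_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.randomized_positions:
            object.__setattr__(
                self,
                "randomized_positions",
                tuple(
                    i
                    for i, aa in enumerate(self.constant_sequence)
                    if aa == self.placeholder
                ),
            )
        if not self.alphabet:
            raise ValueError("alphabet must be non-empty")
        if self.placeholder in self.alphabet:
            raise ValueError("placeholder must not be in the alphabet")
        for i in self.randomized_positions:
            if not (0 <= i < len(self.constant_sequence)):
                raise ValueError(f"randomized position {i} out of range")
            if self.constant_sequence[i] != self.placeholder:
                raise ValueError(
                    f"position {i} does not hold placeholder {self.placeholder!r}"
                )

    @property
    def n_randomized(self) -> int:
        return len(self.randomized_positions)

    @property
    def is_contiguous(self) -> bool:
        """True when the randomized positions form one uninterrupted block."""
        p = self.randomized_positions
        return len(p) == 0 or p[-1] - p[0] + 1 == len(p)


# --- built-in templates -----------------------------------------------------

_LOOP_CONSTANT = (
    "MKSPEELKRIFEKYAAKEGDPDQLSKDELKLLIQAEFPSLLKGM"
    "GGG" + PLACEHOLDER * 7 + "GGG"
    "STLDDLFQELDKDGDGEVSFEEFQVLVKKISQ"
)
_SIDE_CONSTANT = (
    "MKSPEELKRIFEKYAAKEGDPDQLS"
    + PLACEHOLDER * 2 + "EL" + PLACEHOLDER * 2 + "LI" + PLACEHOLDER * 2 +
    "EFPSLLKGMSTLDDLFQELDKDGDGEVSFEEFQVLVKKISQ"
)

#: Number of constant residues on each side of the variable block whose codons
#: serve as the DNA flank markers.
FLANK_RESIDUES = 4


def _derive_flanks(
    constant: str, positions: Sequence[int], design: CodonDesign
) -> tuple[str, str]:
    first, last = positions[0], positions[-1]
    lo = max(0, first - FLANK_RESIDUES)
    hi = min(len(constant), last + 1 + FLANK_RESIDUES)
    f5 = "".join(design.codon_for(aa) for aa in constant[lo:first])
    f3 = "".join(design.codon_for(aa) for aa in constant[last + 1 : hi])
    return f5, f3


def builtin_template(
    name: str, codon_design: Optional[CodonDesign] = None
) -> ScaffoldTemplate:
    """Built-in ``loop`` (7 randomized positions) or ``side`` (6) template."""
    design = codon_design or CodonDesign()
    constants = {"loop": _LOOP_CONSTANT, "side": _SIDE_CONSTANT}
    try:
        constant = constants[name]
    except KeyError:
        raise KeyError(f"unknown built-in template {name!r}") from None
    positions = tuple(i for i, aa in enumerate(constant) if aa == PLACEHOLDER)
    f5, f3 = _derive_flanks(constant, positions, design)
    tmpl = ScaffoldTemplate(
        name=name, constant_sequence=constant, dna_flank_5p=f5, dna_flank_3p=f3
    )
    expected = {"loop": 7, "side": 6}[name]
    assert tmpl.n_randomized == expected
    return tmpl


def load_template(path: str | Path) -> ScaffoldTemplate:
    """Load a user-defined template from a JSON config file."""
    cfg = json.loads(Path(path).read_text())
    return ScaffoldTemplate(
        name=cfg["name"],
        constant_sequence=cfg["constant_sequence"],
        dna_flank_5p=cfg.get("dna_flank_5p", ""),
        dna_flank_3p=cfg.get("dna_flank_3p", ""),
        placeholder=cfg.get("placeholder", PLACEHOLDER),
        alphabet=frozenset(cfg.get("alphabet", sorted(DEFAULT_ALPHABET))),
    )


# --- operations -------------------------------------------------------------


def theoretical_diversity(template: ScaffoldTemplate) -> int:
    """Exact number of distinct variable regions: |alphabet| ** n_randomized."""
    return len(template.alphabet) ** template.n_randomized


def build_variant_protein(
    template: ScaffoldTemplate,
    variable_seq: str,
    allow_extra: Iterable[str] = (),
) -> str:
    """Replace the template placeholders, in order, with ``variable_seq``.

    ``allow_extra`` can admit letters outside the template alphabet (e.g. Q
    read through an amber codon when the alphabet itself excludes Q).
    """
    if len(variable_seq) != template.n_randomized:
        raise ValueError(
            f"variable region length {len(variable_seq)} != "
            f"{template.n_randomized} randomized positions"
        )
    allowed = set(template.alphabet) | set(allow_extra)
    bad = set(variable_seq) - allowed
    if bad:
        raise ValueError(f"disallowed letters in variable region: {sorted(bad)}")
    chars = list(template.constant_sequence)
    for pos, aa in zip(template.randomized_positions, variable_seq):
        chars[pos] = aa
    return "".join(chars)


def extract_variable_region(template: ScaffoldTemplate, protein: str) -> str:
    """Inverse of :func:`build_variant_protein`: letters at randomized positions."""
    if len(protein) != len(template.constant_sequence):
        raise ValueError("protein length does not match template")
    return "".join(protein[i] for i in template.randomized_positions)


def variable_codon_spans(template: ScaffoldTemplate) -> list[tuple[int, int]]:
    """Nucleotide (start, end) spans of each variable codon in construct DNA."""
    return [(3 * i, 3 * i + 3) for i in template.randomized_positions]


def construct_dna(
    template: ScaffoldTemplate,
    design: CodonDesign,
    variable_seq: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Full coding DNA for a variant (or with ``NNN`` at variable codons).

    Constant residues always use the deterministic first-listed codon so that
    constant-region checks have a single expected sequence; variable residues
    are drawn uniformly over permitted codons when an ``rng`` is supplied.
    """
    if variable_seq is not None and len(variable_seq) != template.n_randomized:
        raise ValueError("variable region length mismatch")
    var_iter = iter(variable_seq or "")
    out = []
    for i, aa in enumerate(template.constant_sequence):
        if i in template.randomized_positions:
            if variable_seq is None:
                out.append("NNN")
            else:
                v = next(var_iter)
                cods = design.codons.get(v)
                if not cods:
                    raise KeyError(f"no codon for variable residue {v!r}")
                if rng is None or len(cods) == 1:
                    out.append(cods[0])
                else:
                    out.append(cods[int(rng.integers(len(cods)))])
        else:
            out.append(design.codon_for(aa))
    return "".join(out)


class PrimerSiteError(ValueError):
    """Raised when a primer site is absent or not unique."""

    def __init__(self, primer_name: str, n_sites: int):
        self.primer_name = primer_name
        self.n_sites = n_sites
        super().__init__(
            f"{primer_name} primer found {n_sites} times (expected exactly 1)"
        )


def _find_once(dna: str, site: str, name: str) -> int:
    n = dna.count(site)
    if n != 1:
        raise PrimerSiteError(name, n)
    return dna.index(site)


def find_amplicon(dna: str, fwd_primer: str, rev_primer: str) -> tuple[str, int]:
    """PCR amplicon: forward primer site through reverse primer site, inclusive.

    The reverse primer anneals to the sense strand as its reverse complement,
    downstream of the forward site.  Returns (amplicon sequence, length in bp).
    """
    i = _find_once(dna, fwd_primer, "forward")
    rev_site = reverse_complement(rev_primer)
    n = dna.count(rev_site)
    if n != 1:
        raise PrimerSiteError("reverse", n)
    j = dna.index(rev_site)
    if j < i:
        raise PrimerSiteError("reverse", 0)
    amplicon = dna[i : j + len(rev_site)]
    return amplicon, len(amplicon)
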