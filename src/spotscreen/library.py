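"""Degenerate-codon mathematics for directed-evolution libraries.

A degenerate codon is an IUPAC-coded mixture of DNA triplets (e.g. RBT =
{A/G}{C/G/T}T) synthesized at one mutagenised position; it encodes a
reduced amino-acid alphabet, shrinking the library a screen must cover.
Two statistics matter when planning a screen:

* the **library size** V — the number of distinct amino-acid combinations
  across all randomized positions (duplicate codons for one residue
  collapse at the amino-acid level);
* the **clones required** for coverage — assuming equiprobable variants,
  the probability a fixed variant is missed by n clones is (1 - 1/V)^n, so
  reaching confidence F for any given variant requires

      n = ln(1 - F) / ln(1 - 1/V).

The equiprobable per-variant form is the default because it is the
standard screening-effort estimate; full coupon-collector coverage (every
variant seen) is a stricter and much larger number, deliberately not
computed here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "DegenerateCodon",
    "LibraryDesign",
    "expand_codon",
    "library_size",
    "codon_level_size",
    "clones_for_coverage",
    "design_library",
]

STOP = "*"


@dataclass(frozen=True)
class DegenerateCodon:
    """One randomized position: IUPAC code, expanded codons, encoded residues."""

    code: str
    codons: tuple[str, ...]
    residues: frozenset[str]
    has_stop: bool

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    @property
    def n_residues(self) -> int:
        """Distinct amino acids, stops excluded."""
        return len(self.residues - {STOP})


def expand_codon(code: str) -> DegenerateCodon:
    """Expand a 3-letter IUPAC degenerate codon to codons and residues.

    E.g. ``RBT`` expands to {ACT, AGT, ATT, GCT, GGT, GTT}, encoding the six
    residues {T, S, I, A, G, V}.
    """
    if not isinstance(code, str) or len(code) != 3:
        raise ValueError(f"degenerate codon must be 3 IUPAC symbols, got {code!r}")
    code = code.upper()
    expansions = []
    for sym in code:
        if sym not in ambiguous_dna_values:
            raise ValueError(f"invalid IUPAC nucleotide symbol {sym!r} in {code!r}")
        expansions.append(ambiguous_dna_values[sym])
    codons = tuple(sorted("".join(c) for c in itertools.product(*expansions)))
    residues = frozenset(
        standard_dna_table.forward_table.get(c, STOP) for c in codons
    )
    return DegenerateCodon(code=code, codons=codons, residues=residues,
                           has_stop=STOP in residues)


def library_size(positions: list[DegenerateCodon]) -> int:
    """Amino-acid-level library size: product of per-position residue counts.

    Duplicate codons encoding the same residue collapse; stop codons do not
    count toward the variant total.  A position encoding only stops is
    rejected.
    """
    if not positions:
        raise ValueError("library needs at least one randomized position")
    v = 1
    for p in positions:
        if p.n_residues == 0:
            raise ValueError(f"position {p.code} encodes only stop codons")
        v *= p.n_residues
    return v


def codon_level_size(positions: list[DegenerateCodon]) -> int:
    """DNA-level combination count (product of per-position codon counts)."""
    if not positions:
        raise ValueError("library needs at least one randomized position")
    v = 1
    for p in positions:
        v *= p.n_codons
    return v


def clones_for_coverage(f: float, v: int, rounding: str = "nearest") -> int:
    """Clones to screen so a fixed variant appears with confidence F.

    Assumes V equiprobable variants: n = ln(1-F) / ln(1-1/V).  ``rounding``
    is "nearest" (default) or "ceil".  V = 1 needs exactly one clone.
    """
    if not (0.0 < f < 1.0):
        raise ValueError("coverage fraction must lie strictly in (0, 1)")
    if v < 1:
        raise ValueError("variant count must be >= 1")
    if v == 1:
        return 1
    n = math.log(1.0 - f) / math.log(1.0 - 1.0 / v)
    if rounding == "nearest":
        return round(n)
    if rounding == "ceil":
        return math.ceil(n)
    raise ValueError("rounding must be 'nearest' or 'ceil'")


@dataclass(frozen=True)
class LibraryDesign:
    """A multi-position degenerate-codon library with coverage statistics."""

    positions: tuple[DegenerateCodon, ...]
    variant_count: int
    coverage_fraction: float
    clones_required: int

    def __post_init__(self) -> None:
        expected = 1
        for p in self.positions:
            expected *= p.n_residues
        if self.variant_count != expected:
            raise ValueError("variant_count inconsistent with positions")
        if not (0.0 < self.coverage_fraction < 1.0):
            raise ValueError("coverage_fraction must lie in (0, 1)")


def design_library(codes: list[str], coverage: float = 0.95) -> LibraryDesign:
    """Expand codes, compute the variant count, and size the screen."""
    positions = tuple(expand_codon(c) for c in codes)
    v = library_size(list(positions))
    return LibraryDesign(positions=positions, variant_count=v,
                         coverage_fraction=coverage,
                         clones_required=clones_for_coverage(coverage, v))
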