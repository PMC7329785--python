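"""IUPAC degenerate-nucleotide algebra.

A degenerate codon is a triplet of IUPAC ambiguity symbols standing for the
cartesian product of the per-position base sets (e.g. NNS = 4*4*2 = 32
concrete codons, MRN = 2*2*4 = 16).  This module expands such codons,
reverse-complements IUPAC strings, translates concrete DNA, and derives the
exact per-codon amino-acid distribution by enumeration.

Probabilities are computed as exact rationals (:class:`fractions.Fraction`)
so that values like 6/16 survive arithmetic unchanged; floats are produced
only at presentation time.  The genetic code and the IUPAC symbol table are
shipped as plain-text data files and loaded at import.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from importlib import resources
from itertools import product
from typing import Iterable, Mapping

from .errors import (
    AmbiguousBaseError,
    DegenerateDistributionError,
    FrameError,
    InvalidAlphabetError,
)

STOP = "*"
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

_BASE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _load_rows(name: str) -> list[list[str]]:
    text = resources.files("cdr3kit.data").joinpath(name).read_text()
    rows = [line.split("\t") for line in text.strip().splitlines()]
    return rows[1:]  # drop header


#: IUPAC nucleotide symbol -> set of concrete bases.
IUPAC_BASES: Mapping[str, frozenset[str]] = {
    sym: frozenset(bases) for sym, bases in _load_rows("iupac_nucleotides.tsv")
}

#: Concrete codon -> one-letter amino acid, stops as ``*``.
GENETIC_CODE: Mapping[str, str] = {
    codon: aa for codon, aa in _load_rows("genetic_code_standard.tsv")
}

# The complement of an ambiguity symbol is the symbol whose base set is the
# elementwise complement; built here so the involution holds by construction.
_SET_TO_SYMBOL = {bases: sym for sym, bases in IUPAC_BASES.items()}
IUPAC_COMPLEMENT: Mapping[str, str] = {
    sym: _SET_TO_SYMBOL[frozenset(_BASE_COMPLEMENT[b] for b in bases)]
    for sym, bases in IUPAC_BASES.items()
}


def canonicalize(seq: str) -> str:
    """Upper-case ``seq``, map U to T, and validate against the IUPAC
    alphabet.

    Raises
    ------
    InvalidAlphabetError
        If any symbol is not an IUPAC nucleotide code.
    """
    seq = seq.upper().replace("U", "T")
    for sym in seq:
        if sym not in IUPAC_BASES:
            raise InvalidAlphabetError(f"invalid IUPAC nucleotide symbol: {sym!r}")
    return seq


def is_degenerate(symbol: str) -> bool:
    """True if ``symbol`` stands for more than one base."""
    return len(IUPAC_BASES[symbol]) > 1


def expand_codon(codon: str) -> frozenset[str]:
    """Expand a degenerate codon into its set of concrete codons.

    >>> len(expand_codon("MRN"))
    16
    """
    codon = canonicalize(codon)
    if len(codon) != 3:
        raise FrameError(f"a codon has three symbols, got {len(codon)}")
    return frozenset(
        "".join(bases) for bases in product(*(IUPAC_BASES[s] for s in codon))
    )


def expand_sequence(seq: str) -> frozenset[str]:
    """Expand an arbitrary IUPAC string into its set of concrete sequences.

    Intended for small windows; the result grows as the product of the
    per-symbol set sizes.
    """
    seq = canonicalize(seq)
    return frozenset(
        "".join(bases) for bases in product(*(IUPAC_BASES[s] for s in seq))
    )


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC string (length-preserving involution)."""
    seq = canonicalize(seq)
    return "".join(IUPAC_COMPLEMENT[s] for s in reversed(seq))


def translate(dna: str) -> str:
    """Translate concrete-base DNA with the standard genetic code.

    Stops are rendered as ``*``.  Ambiguous symbols and out-of-frame lengths
    are rejected; use :func:`codon_aa_distribution` for degenerate codons.
    """
    dna = canonicalize(dna)
    if any(sym not in "ACGT" for sym in dna):
        bad = next(sym for sym in dna if sym not in "ACGT")
        raise AmbiguousBaseError(
            f"translate requires concrete bases; got ambiguous symbol {bad!r}"
        )
    if len(dna) % 3 != 0:
        raise FrameError(f"sequence length {len(dna)} is not a multiple of 3")
    return "".join(GENETIC_CODE[dna[i : i + 3]] for i in range(0, len(dna), 3))


@dataclass(frozen=True)
class AminoAcidDistribution:
    """Exact per-residue probability for one degenerate codon.

    ``exact`` maps each of the 20 standard residues plus ``*`` (stop) to a
    :class:`~fractions.Fraction`; entries not encoded by the codon are 0.
    When ``conditioned_on_sense`` is true the stop mass has been removed and
    the remaining mass renormalized, so ``exact[STOP] == 0``.
    """

    exact: Mapping[str, Fraction]
    conditioned_on_sense: bool

    def __post_init__(self) -> None:
        total = sum(self.exact.values())
        if total != 1:
            raise ValueError(f"distribution mass is {total}, expected 1")

    def __getitem__(self, residue: str) -> float:
        return float(self.exact[residue])

    @property
    def probabilities(self) -> dict[str, float]:
        """Float view of the distribution."""
        return {aa: float(p) for aa, p in self.exact.items()}

    @property
    def stop_probability(self) -> Fraction:
        return self.exact[STOP]

    def mass(self, residues: Iterable[str]) -> Fraction:
        """Exact total probability of a set of residues."""
        return sum((self.exact[r] for r in set(residues)), Fraction(0))

    def support(self) -> frozenset[str]:
        """Residues (excluding stop) with nonzero probability."""
        return frozenset(
            aa for aa, p in self.exact.items() if p > 0 and aa != STOP
        )


@lru_cache(maxsize=None)
def codon_aa_distribution(
    codon: str, conditioned_on_sense: bool = False
) -> AminoAcidDistribution:
    """Exact amino-acid distribution of a degenerate codon by enumeration.

    Each concrete codon in the expansion is equiprobable, so
    P(residue) = (#codons translating to it) / (expansion size).  With
    ``conditioned_on_sense`` the stop codons are dropped before
    normalization, giving the distribution among translatable (sense)
    choices only.

    >>> d = codon_aa_distribution("MRN")
    >>> d.mass("RKH")
    Fraction(5, 8)
    """
    concrete = expand_codon(codon)
    counts: dict[str, int] = {aa: 0 for aa in AMINO_ACIDS}
    counts[STOP] = 0
    for c in concrete:
        counts[GENETIC_CODE[c]] += 1
    if conditioned_on_sense:
        n_sense = len(concrete) - counts[STOP]
        if n_sense == 0:
            raise DegenerateDistributionError(
                f"all {len(concrete)} concrete codons of {codon!r} are stops"
            )
        counts[STOP] = 0
        exact = {aa: Fraction(n, n_sense) for aa, n in counts.items()}
    else:
        exact = {aa: Fraction(n, len(concrete)) for aa, n in counts.items()}
    return AminoAcidDistribution(exact=exact, conditioned_on_sense=conditioned_on_sense)
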