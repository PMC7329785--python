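"""Consensus-motif patterns over CDR3 positions.

Heparin-binding consensus sites are written with position classes: ``B`` is
a basic residue {R, K, H}, ``Z`` the extended basic-like class
{R, K, H, N, Q, S}, and ``X`` any of the 20 standard residues.  Literal
residues may appear directly (``G``, ``P``) and small alternations as
``(R/K)``.  A pattern is an ordered list of allowed-residue sets; matching
is positionwise set membership, and the theoretical match probability under
a library scheme is the exact product of per-position allowed-mass terms.

By default probabilities are conditional on full-length (stop-free)
translation, which is the denominator used when tabulating motif content
among sequenced full-length clones; the unconditional variant is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

from .codons import AMINO_ACIDS, STOP, codon_aa_distribution
from .errors import MotifLengthError, NotFullLengthError, PatternParseError
from .scheme import LibraryScheme

#: Built-in position classes. B is strictly basic; the broader Z class is a
#: distinct symbol, never a widening of B.
DEFAULT_CLASSES: Mapping[str, frozenset[str]] = {
    "B": frozenset("RKH"),
    "Z": frozenset("RKHNQS"),
    "X": frozenset(AMINO_ACIDS),
}


@dataclass(frozen=True)
class MotifPattern:
    """Per-position allowed-residue sets with a display name."""

    name: str
    positions: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        for i, allowed in enumerate(self.positions, start=1):
            if not allowed:
                raise ValueError(f"position {i} of {self.name!r} allows no residue")
            bad = allowed - set(AMINO_ACIDS)
            if bad:
                raise ValueError(
                    f"position {i} of {self.name!r} allows non-standard "
                    f"residues {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.positions)


def parse_pattern(
    text: str, class_definitions: Mapping[str, frozenset[str]] | None = None
) -> MotifPattern:
    """Parse a pattern string like ``XBBXBX`` or ``GZZP(R/K)X``.

    Each character is looked up in the class definitions first; characters
    that are not class symbols but are standard residues become singleton
    sets.  ``(A/B/...)`` groups allow any of the listed residues.

    >>> parse_pattern("GZZP(R/K)X").positions[4] == frozenset("RK")
    True
    """
    classes = DEFAULT_CLASSES if class_definitions is None else class_definitions
    positions: list[frozenset[str]] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "(":
            end = text.find(")", i)
            if end < 0:
                raise PatternParseError(f"unclosed '(' at position {i} in {text!r}")
            residues = frozenset(text[i + 1 : end].split("/"))
            bad = residues - set(AMINO_ACIDS)
            if bad:
                raise PatternParseError(
                    f"unknown residues {sorted(bad)} in group at position {i}"
                )
            positions.append(residues)
            i = end + 1
        elif ch in classes:
            positions.append(frozenset(classes[ch]))
            i += 1
        elif ch in AMINO_ACIDS:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise PatternParseError(
                f"unknown class symbol {ch!r} at position {i} in {text!r}"
            )
    return MotifPattern(name=text, positions=tuple(positions))


def match(cdr3: str, pattern: MotifPattern) -> bool:
    """Positionwise set-membership match of a CDR3 peptide against a pattern.

    Raises
    ------
    NotFullLengthError
        If the peptide contains a stop/terminator symbol.
    MotifLengthError
        If peptide and pattern lengths differ.
    """
    if STOP in cdr3:
        raise NotFullLengthError(f"terminator in CDR3 {cdr3!r}")
    if len(cdr3) != len(pattern):
        raise MotifLengthError(
            f"CDR3 length {len(cdr3)} != pattern length {len(pattern)}"
        )
    return all(res in allowed for res, allowed in zip(cdr3, pattern.positions))


def theoretical_probability_exact(
    pattern: MotifPattern,
    scheme: LibraryScheme,
    conditional_on_full_length: bool = True,
) -> Fraction:
    """Exact motif-match probability under a scheme, as a Fraction.

    The scheme is a per-codon cartesian product, so the probability is the
    product over positions of the allowed-residue mass of that codon's
    amino-acid distribution (stop-conditioned when
    ``conditional_on_full_length``).
    """
    if len(pattern) != len(scheme):
        raise MotifLengthError(
            f"pattern length {len(pattern)} != scheme length {len(scheme)}"
        )
    prob = Fraction(1)
    for allowed, codon in zip(pattern.positions, scheme.codons):
        dist = codon_aa_distribution(
            codon, conditioned_on_sense=conditional_on_full_length
        )
        prob *= dist.mass(allowed)
    return prob


def theoretical_probability(
    pattern: MotifPattern,
    scheme: LibraryScheme,
    conditional_on_full_length: bool = True,
) -> float:
    """Float view of :func:`theoretical_probability_exact`.

    >>> from .scheme import xbbxbx_scheme
    >>> round(theoretical_probability(parse_pattern("XBBXBX"), xbbxbx_scheme()), 4)
    0.2441
    """
    return float(
        theoretical_probability_exact(pattern, scheme, conditional_on_full_length)
    )
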