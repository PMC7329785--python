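"""Randomized-CDR3 library schemes and exact diversity calculus.

A :class:`LibraryScheme` is the ordered list of degenerate codons spanning
the randomized CDR3 window, written on the coding strand.  Schemes are
usually derived from a degenerate oligonucleotide primer: the maximal run of
ambiguous symbols is the randomized window, and if the primer anneals to the
antisense strand the window is reverse-complemented before codon splitting.

The heparin-binding-consensus library studied here was built from an 87-nt
antisense primer whose degenerate window reads SNN NYK SNN NYK NYK SNN,
i.e. NNS MRN MRN NNS MRN NNS on the coding strand: six codons encoding an
XBBXBX-biased hexapeptide.  Because the window is a per-codon cartesian
product, DNA diversity, protein diversity and the stop-free fraction all
factor exactly over positions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction

from . import codons as cd
from .errors import AmbiguousWindowError, EmptySampleError, FrameError

#: Antisense degenerate primer used to engineer the XBBXBX-biased CDR3
#: (written 5'->3'; FR4 segment, 18-nt degenerate window, FR3 segment).
CDR3_PRIMER = (
    "GCCTCCACCTCTCGAGACGGTGACCAGGGTACCTTGGCCCCA"
    "SNNNYKSNNNYKNYKSNN"
    "TCTTGCACAGTAATACAGGGCCGTGTC"
)
CDR3_PRIMER_NAME = "CDR3 primer"


@dataclass(frozen=True)
class LibraryScheme:
    """Ordered degenerate codons of a randomized window, coding strand.

    ``fr3_flank``/``fr4_flank`` hold the fixed coding-strand sequences
    immediately up- and downstream of the window when the scheme was derived
    from a primer; they double as anchor defaults for CDR3 extraction.
    """

    codons: tuple[str, ...]
    provenance: str = ""
    fr3_flank: str | None = None
    fr4_flank: str | None = None

    def __post_init__(self) -> None:
        if len(self.codons) < 1:
            raise ValueError("a scheme needs at least one codon")
        object.__setattr__(
            self, "codons", tuple(cd.canonicalize(c) for c in self.codons)
        )
        for c in self.codons:
            if len(c) != 3:
                raise FrameError(f"scheme codon {c!r} is not a triplet")

    def __len__(self) -> int:
        return len(self.codons)

    @property
    def window(self) -> str:
        """The degenerate window as one IUPAC string."""
        return "".join(self.codons)

    @property
    def window_length(self) -> int:
        """Window length in nucleotides."""
        return 3 * len(self.codons)

    def to_primer(self, strand: str = "sense") -> str:
        """Reassemble a primer string (flanks + window) on the given strand."""
        seq = (self.fr3_flank or "") + self.window + (self.fr4_flank or "")
        return seq if strand == "sense" else cd.reverse_complement(seq)


def _degenerate_runs(seq: str) -> list[tuple[int, int]]:
    """Half-open index ranges of maximal runs of non-ACGT symbols."""
    runs, start = [], None
    for i, sym in enumerate(seq):
        if sym not in "ACGT":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def scheme_from_primer(
    primer: str, strand: str = "sense", name: str = ""
) -> LibraryScheme:
    """Derive a :class:`LibraryScheme` from a degenerate primer.

    The primer must contain exactly one maximal run of ambiguous (non-ACGT)
    symbols, of length divisible by three.  For ``strand="antisense"`` the
    whole primer is reverse-complemented first, so the returned codons and
    flanks are in coding-strand order.

    Raises
    ------
    AmbiguousWindowError
        Zero or multiple degenerate runs.
    FrameError
        Run length not a multiple of three.
    """
    if strand not in ("sense", "antisense"):
        raise ValueError(f"strand must be 'sense' or 'antisense', got {strand!r}")
    seq = cd.canonicalize(primer)
    if strand == "antisense":
        seq = cd.reverse_complement(seq)
    runs = _degenerate_runs(seq)
    if len(runs) != 1:
        raise AmbiguousWindowError(
            f"expected exactly one degenerate window, found {len(runs)}"
        )
    lo, hi = runs[0]
    if (hi - lo) % 3 != 0:
        raise FrameError(f"degenerate window length {hi - lo} is not a multiple of 3")
    window = seq[lo:hi]
    return LibraryScheme(
        codons=tuple(window[i : i + 3] for i in range(0, len(window), 3)),
        provenance=f"{name or 'primer'} ({strand} strand)",
        fr3_flank=seq[:lo] or None,
        fr4_flank=seq[hi:] or None,
    )


def xbbxbx_scheme() -> LibraryScheme:
    """The published XBBXBX CDR3 scheme: NNS MRN MRN NNS MRN NNS."""
    return scheme_from_primer(CDR3_PRIMER, strand="antisense", name=CDR3_PRIMER_NAME)


@dataclass(frozen=True)
class DiversityReport:
    """Exact combinatorial diversity of a scheme.

    ``dna_diversity`` counts distinct concrete DNA windows;
    ``protein_diversity`` counts distinct stop-free proteins (the product of
    per-codon sense-residue support sizes — exact because positions are
    independent); ``stop_free_fraction`` is the probability that a uniformly
    drawn DNA window translates without a stop.
    """

    dna_diversity: int
    protein_diversity: int
    stop_free_fraction_exact: Fraction
    per_position_distributions: tuple[cd.AminoAcidDistribution, ...] = field(
        repr=False
    )

    @property
    def stop_free_fraction(self) -> float:
        return float(self.stop_free_fraction_exact)

    def to_dict(self) -> dict:
        return {
            "dna_diversity": self.dna_diversity,
            "protein_diversity": self.protein_diversity,
            "stop_free_fraction": self.stop_free_fraction,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def diversity(scheme: LibraryScheme) -> DiversityReport:
    """Exact diversity of a scheme by per-position enumeration.

    >>> report = diversity(xbbxbx_scheme())
    >>> report.dna_diversity, report.protein_diversity
    (134217728, 1728000)
    """
    dists = tuple(cd.codon_aa_distribution(c) for c in scheme.codons)
    dna = math.prod(len(cd.expand_codon(c)) for c in scheme.codons)
    protein = math.prod(len(d.support()) for d in dists)
    stop_free = math.prod(
        (1 - d.stop_probability for d in dists), start=Fraction(1)
    )
    return DiversityReport(
        dna_diversity=dna,
        protein_diversity=protein,
        stop_free_fraction_exact=stop_free,
        per_position_distributions=dists,
    )


@dataclass(frozen=True)
class LibrarySizeEstimate:
    """Uniqueness-based heuristic estimate of realized library size.

    The estimator scales the theoretical diversity by the observed fraction
    of unique sequences among sequenced full-length clones.  It is a crude
    saturation heuristic, not a richness estimator, and is documented as
    such.
    """

    fraction_unique: float
    estimated_clones: float
    estimated_proteins: float

    def to_dict(self) -> dict:
        return {
            "fraction_unique": self.fraction_unique,
            "estimated_clones": self.estimated_clones,
            "estimated_proteins": self.estimated_proteins,
        }


def library_size_estimate(
    n_full: int, n_unique: int, report: DiversityReport
) -> LibrarySizeEstimate:
    """Scale theoretical diversity by the observed unique fraction.

    >>> est = library_size_estimate(194, 189, diversity(xbbxbx_scheme()))
    >>> format_scientific(est.estimated_clones)
    '1.31 x 10^8'
    """
    if n_full == 0:
        raise EmptySampleError("no full-length clones sequenced")
    if not 0 < n_unique <= n_full:
        raise ValueError(f"need 0 < n_unique <= n_full, got {n_unique}/{n_full}")
    frac = Fraction(n_unique, n_full)
    return LibrarySizeEstimate(
        fraction_unique=float(frac),
        estimated_clones=float(frac * report.dna_diversity),
        estimated_proteins=float(frac * report.protein_diversity),
    )


def format_scientific(x: float, sig: int = 3) -> str:
    """Format a count in ``m.mm x 10^e`` style with ``sig`` significant digits."""
    if x == 0:
        return "0"
    exp = math.floor(math.log10(abs(x)))
    mantissa = round(x / 10**exp, sig - 1)
    if abs(mantissa) >= 10:  # rounding carried over
        mantissa /= 10
        exp += 1
    return f"{mantissa:.{sig - 1}f} x 10^{exp}"
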