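"""Clone sequence analysis: CDR3 extraction, summaries, enrichment.

Clone DNA sequences (typically Sanger reads of randomly picked or
biopanning-selected phagemids) are scanned for the fixed framework anchors
flanking the randomized CDR3 window.  A clone is *full length* when both
anchors are found, the window between them has the expected length
(3 x scheme length) and translates without a stop.  Summaries follow the
conventions of library quality-control tables: uniqueness at the CDR3 DNA
level, motif percentages with unique full-length sequences as denominator.

Motif enrichment between a selected and a reference clone set is tested
with Fisher's exact test (two-sided, point-probability rule) computed in
exact rational arithmetic; a chi-square test with continuity correction is
available as an alternative.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb, inf, isnan, nan
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from . import codons as cd
from .errors import DegenerateTableError, EmptySampleError, MotifLengthError
from .motif import MotifPattern, match
from .scheme import LibraryScheme

#: Residue row order for position-frequency CSV output (library QC style:
#: A and D first, then N, R and the remaining residues).
RESIDUE_ORDER: tuple[str, ...] = tuple("ADNRCQEGHILKMFPSTWYV")


@dataclass
class CloneRecord:
    """One sequenced clone with derived CDR3 annotations.

    ``cdr3_dna``/``cdr3_protein`` are None when the window could not be
    located; ``motif_matches`` maps pattern name -> bool for full-length
    clones (empty otherwise).
    """

    identifier: str
    dna: str
    cdr3_dna: str | None = None
    cdr3_protein: str | None = None
    full_length: bool = False
    motif_matches: dict[str, bool] = field(default_factory=dict)


def extract_cdr3(
    dna: str, fr3_anchor: str, fr4_anchor: str, window_len: int
) -> str | None:
    """Substring strictly between the first FR3 anchor and the following
    FR4 anchor, or None if either anchor is absent.

    Anchor matching is exact and case-insensitive; no mismatches are
    tolerated.  Multiple FR3 anchor hits trigger a warning and the first
    hit is used.  The returned window is *not* validated here — frame and
    stop checks happen in :func:`analyze_clones`.
    """
    dna = dna.upper()
    fr3 = fr3_anchor.upper()
    fr4 = fr4_anchor.upper()
    start = dna.find(fr3)
    if start < 0:
        return None
    if dna.find(fr3, start + 1) >= 0:
        warnings.warn(
            f"multiple FR3 anchor hits; using the first at {start}", stacklevel=2
        )
    lo = start + len(fr3)
    hi = dna.find(fr4, lo)
    if hi < 0:
        return None
    return dna[lo:hi]


def read_clone_fasta(path: str | Path) -> list[CloneRecord]:
    """Read clone DNA from FASTA into bare :class:`CloneRecord` objects."""
    return [
        CloneRecord(identifier=rec.id, dna=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def analyze_clones(
    clones: Iterable[CloneRecord] | str | Path,
    scheme: LibraryScheme,
    patterns: Sequence[MotifPattern] = (),
    fr3_anchor: str | None = None,
    fr4_anchor: str | None = None,
) -> list[CloneRecord]:
    """Annotate clones with CDR3 window, translation, full-length flag and
    motif matches.

    Anchors default to the scheme's framework flanks.  A clone is full
    length iff both anchors are found, the window length equals
    ``scheme.window_length``, the window is concrete DNA, and its
    translation is stop-free.
    """
    if isinstance(clones, (str, Path)):
        clones = read_clone_fasta(clones)
    fr3 = fr3_anchor or scheme.fr3_flank
    fr4 = fr4_anchor or scheme.fr4_flank
    if not fr3 or not fr4:
        raise ValueError("anchors required: scheme has no flanks and none given")
    out = []
    for clone in clones:
        window = extract_cdr3(clone.dna, fr3, fr4, scheme.window_length)
        clone.cdr3_dna = window
        clone.cdr3_protein = None
        clone.full_length = False
        clone.motif_matches = {}
        if window is not None and len(window) == scheme.window_length and all(
            b in "ACGT" for b in window
        ):
            protein = cd.translate(window)
            clone.cdr3_protein = protein
            if cd.STOP not in protein:
                clone.full_length = True
                clone.motif_matches = {p.name: match(protein, p) for p in patterns}
        out.append(clone)
    return out


@dataclass(frozen=True)
class CloneSummary:
    """Library QC summary over a set of analyzed clones.

    Motif counts are over *unique* full-length CDR3 DNA sequences, and the
    percentages use ``n_unique_dna`` as denominator.
    """

    n_selected: int
    n_full_length: int
    n_unique_dna: int
    n_unique_protein: int
    motif_counts: dict[str, int]

    @property
    def percent_full_length(self) -> float:
        return 100.0 * self.n_full_length / self.n_selected

    @property
    def percent_unique(self) -> float:
        return 100.0 * self.n_unique_dna / self.n_full_length

    def motif_percent(self, name: str) -> float:
        return 100.0 * self.motif_counts[name] / self.n_unique_dna

    def to_dict(self) -> dict:
        return {
            "n_selected": self.n_selected,
            "n_full_length": self.n_full_length,
            "n_unique_dna": self.n_unique_dna,
            "n_unique_protein": self.n_unique_protein,
            "percent_full_length": round_half_up(self.percent_full_length),
            "percent_unique": round_half_up(self.percent_unique),
            "motifs": {
                name: {"count": n, "percent": round_half_up(self.motif_percent(name))}
                for name, n in self.motif_counts.items()
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, one decimal by default (table style)."""
    scale = 10**ndigits
    return int(x * scale + (0.5 if x >= 0 else -0.5)) / scale


def summarize(
    clones: Sequence[CloneRecord], patterns: Sequence[MotifPattern] = ()
) -> CloneSummary:
    """Tabulate full-length / uniqueness / motif statistics.

    Uniqueness is computed on the CDR3 DNA of full-length clones (protein
    uniqueness is reported alongside); each motif is counted once per
    unique DNA sequence.
    """
    clones = list(clones)
    if not clones:
        raise EmptySampleError("no clones to summarize")
    full = [c for c in clones if c.full_length]
    unique: dict[str, CloneRecord] = {}
    for c in full:
        unique.setdefault(c.cdr3_dna, c)  # type: ignore[arg-type]
    motif_counts = {
        p.name: sum(
            1 for c in unique.values() if match(c.cdr3_protein, p)  # type: ignore[arg-type]
        )
        for p in patterns
    }
    return CloneSummary(
        n_selected=len(clones),
        n_full_length=len(full),
        n_unique_dna=len(unique),
        n_unique_protein=len({c.cdr3_protein for c in unique.values()}),
        motif_counts=motif_counts,
    )


def position_frequencies(cdr3s: Sequence[str]) -> pd.DataFrame:
    """Residue-by-position percentage matrix over equal-length peptides.

    Rows are the 20 residues in :data:`RESIDUE_ORDER`, columns CDR3
    positions 1..n; each column sums to 100.
    """
    cdr3s = list(cdr3s)
    if not cdr3s:
        raise EmptySampleError("no CDR3 sequences")
    n = len(cdr3s[0])
    for s in cdr3s:
        if len(s) != n:
            raise MotifLengthError(f"mixed CDR3 lengths: {len(s)} vs {n}")
        if cd.STOP in s:
            raise MotifLengthError(f"terminator in CDR3 {s!r}")
    table = pd.DataFrame(
        0.0, index=list(RESIDUE_ORDER), columns=range(1, n + 1)
    )
    for s in cdr3s:
        for pos, res in enumerate(s, start=1):
            table.loc[res, pos] += 1
    return 100.0 * table / len(cdr3s)


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 motif-enrichment comparison between two clone sets."""

    table: tuple[tuple[int, int], tuple[int, int]]  # rows: selected, reference
    odds_ratio: float
    p_value: float
    p_value_exact: Fraction | None
    method: str

    def to_dict(self) -> dict:
        return {
            "table": [list(r) for r in self.table],
            "odds_ratio": None if isnan(self.odds_ratio) else self.odds_ratio,
            "p_value": self.p_value,
            "method": self.method,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher exact p-value by the point-probability rule.

    With both margins fixed, the first cell follows a hypergeometric law;
    the p-value sums the probabilities of all tables whose point
    probability does not exceed that of the observed table.  Exact rational
    arithmetic makes ties unambiguous.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        raise DegenerateTableError(f"zero margin in table {((a, b), (c, d))}")
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmf = {k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom) for k in range(lo, hi + 1)}
    observed = pmf[a]
    return sum((p for p in pmf.values() if p <= observed), Fraction(0))


def enrichment_test(
    selected: tuple[int, int], random: tuple[int, int], method: str = "fisher"
) -> EnrichmentResult:
    """Compare motif fractions between selected and reference clones.

    Parameters are ``(n_match, n_total)`` pairs.  ``method="fisher"`` is the
    exact two-sided test; ``method="chi2"`` is the chi-square test with
    continuity correction (scipy).  The odds ratio is the cross-product
    ad/bc, reported as ``inf``/``0`` (or ``nan`` for 0/0) when a cell is
    empty, never adjusted.
    """
    (m1, n1), (m2, n2) = selected, random
    if not (0 <= m1 <= n1 and 0 <= m2 <= n2 and n1 > 0 and n2 > 0):
        raise ValueError(f"bad counts: {selected} vs {random}")
    a, b, c, d = m1, n1 - m1, m2, n2 - m2
    if b * c:
        odds = a * d / (b * c)
    elif a * d:
        odds = inf
    elif a == 0 and d == 0 and b * c == 0:
        odds = nan
    else:
        odds = 0.0
    if method == "fisher":
        p = fisher_exact_two_sided(a, b, c, d)
        return EnrichmentResult(((a, b), (c, d)), odds, float(p), p, "fisher")
    if method == "chi2":
        from scipy.stats import chi2_contingency

        res = chi2_contingency([[a, b], [c, d]], correction=True)
        return EnrichmentResult(((a, b), (c, d)), odds, float(res.pvalue), None, "chi2")
    raise ValueError(f"unknown method {method!r}")
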