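"""Seeded clone-library simulator with biopanning-style selection.

The generator emulates the statistical structure of a randomly sampled
degenerate-codon phage-display library:

* each CDR3 position draws a uniform base from its IUPAC symbol's base set,
  so every concrete codon within a degenerate codon is equiprobable;
* the CDR3 window is embedded between the fixed framework flanks;
* a configurable fraction of clones is corrupted (1-nt flank deletion,
  3'-truncation before the downstream anchor, or an in-frame stop planted
  in the window) so the analyzer-reported full-length rate hits a target;
* affinity selection is modelled as weighted resampling with replacement:
  a clone's sampling weight is the product of the weights of the motif
  patterns its CDR3 matches.

With a single pattern of weight ``w`` and pre-selection match fraction
``p0``, the expected post-selection fraction is the odds-scaling closed
form ``p1 = w*p0 / (w*p0 + (1 - p0))``; :func:`recover_enrichment_weight`
inverts it.  All randomness flows through one numpy PCG64 stream seeded in
the config, making output byte-identical across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import codons as cd
from .errors import BoundaryError, ConfigError, DegenerateWeightsError
from .motif import MotifPattern, match
from .scheme import LibraryScheme, diversity

RNG_ALGORITHM = "numpy-PCG64"

#: Analyzer-reported full-length fraction emulated by default (fraction of
#: randomly picked clones whose CDR3 window is intact, in frame and
#: stop-free).
DEFAULT_FULL_LENGTH_RATE = 0.873

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated library.

    ``full_length_rate`` is the *analyzer-reported* target: natural in-frame
    stops already remove mass, so the corruption probability applied is
    ``1 - full_length_rate / stop_free_fraction`` and the target cannot
    exceed the scheme's stop-free ceiling.  ``corruption_mix`` gives the
    relative weights of (flank frameshift, 3'-truncation, in-frame stop).
    """

    scheme: LibraryScheme
    n_clones: int
    seed: int = 0
    full_length_rate: float = DEFAULT_FULL_LENGTH_RATE
    corruption_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    fr3_flank: str | None = None
    fr4_flank: str | None = None
    rng_algorithm: str = RNG_ALGORITHM

    def __post_init__(self) -> None:
        if self.fr3_flank is None:
            self.fr3_flank = self.scheme.fr3_flank
        if self.fr4_flank is None:
            self.fr4_flank = self.scheme.fr4_flank
        if not self.fr3_flank or not self.fr4_flank:
            raise ConfigError("scheme has no framework flanks and none given")
        if self.rng_algorithm != RNG_ALGORITHM:
            raise ConfigError(f"unsupported rng algorithm {self.rng_algorithm!r}")
        ceiling = float(diversity(self.scheme).stop_free_fraction_exact)
        if not 0 <= self.full_length_rate <= ceiling + 1e-12:
            raise ConfigError(
                f"full_length_rate {self.full_length_rate} exceeds the "
                f"stop-free ceiling {ceiling:.4f} of this scheme"
            )
        if min(self.corruption_mix) < 0 or sum(self.corruption_mix) == 0:
            raise ConfigError(f"bad corruption mix {self.corruption_mix}")

    @property
    def corruption_probability(self) -> float:
        ceiling = float(diversity(self.scheme).stop_free_fraction_exact)
        return 1.0 - self.full_length_rate / ceiling


@dataclass
class SimulatedClone:
    """A simulated clone with generator-side truth annotations."""

    identifier: str
    dna: str
    cdr3_dna: str
    cdr3_protein: str
    full_length_truth: bool
    corruption: str | None = None
    motif_truth: dict[str, bool] = field(default_factory=dict)

    def fasta_header(self) -> str:
        motifs = (
            ",".join(name for name, hit in self.motif_truth.items() if hit) or "none"
        )
        return f"{self.identifier}|full_length={int(self.full_length_truth)}|motifs={motifs}"


def _sample_windows(scheme: LibraryScheme, n: int, rng: np.random.Generator) -> list[str]:
    """Draw n concrete CDR3 windows, uniform per degenerate position."""
    cols = []
    for sym in scheme.window:
        bases = sorted(cd.IUPAC_BASES[sym])
        cols.append(np.array(bases)[rng.integers(0, len(bases), size=n)])
    stacked = np.stack(cols, axis=1)
    return ["".join(row) for row in stacked]


def sample_library(
    config: SimulationConfig, patterns: Sequence[MotifPattern] = ()
) -> list[SimulatedClone]:
    """Generate a clone library under the configured study conditions.

    Corrupted clones are never analyzer-full-length by construction, so the
    expected reported full-length fraction is
    ``(1 - q) * stop_free_fraction = full_length_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_clones
    windows = _sample_windows(config.scheme, n, rng)
    q = config.corruption_probability
    corrupt = rng.random(n) < q
    mix = np.asarray(config.corruption_mix, dtype=float)
    modes = rng.choice(3, size=n, p=mix / mix.sum())
    fr3, fr4 = config.fr3_flank, config.fr4_flank
    clones: list[SimulatedClone] = []
    for i in range(n):
        window = windows[i]
        protein = cd.translate(window)
        natural_full = cd.STOP not in protein
        corruption: str | None = None
        dna = fr3 + window + fr4
        if corrupt[i]:
            mode = int(modes[i])
            if mode == 0:  # 1-nt deletion in the upstream flank
                pos = int(rng.integers(0, len(fr3)))
                dna = fr3[:pos] + fr3[pos + 1 :] + window + fr4
                corruption = "frameshift"
            elif mode == 1:  # 3'-truncation before the downstream anchor
                keep = int(rng.integers(0, min(len(fr4), 6)))
                dna = fr3 + window + fr4[:keep]
                corruption = "truncation"
            else:  # in-frame stop planted in the window
                codon_i = int(rng.integers(0, len(config.scheme)))
                stop = STOP_CODONS[int(rng.integers(0, 3))]
                window = (
                    window[: 3 * codon_i] + stop + window[3 * codon_i + 3 :]
                )
                protein = cd.translate(window)
                dna = fr3 + window + fr4
                corruption = "stop_substitution"
        full = corruption is None and natural_full
        clones.append(
            SimulatedClone(
                identifier=f"clone{i + 1:06d}",
                dna=dna,
                cdr3_dna=window,
                cdr3_protein=protein,
                full_length_truth=full,
                corruption=corruption,
                motif_truth={p.name: full and match(protein, p) for p in patterns},
            )
        )
    return clones


def write_fasta(clones: Sequence[SimulatedClone], path: str | Path) -> None:
    """Write clones as FASTA with truth-tracking headers."""
    with open(path, "w") as fh:
        for clone in clones:
            fh.write(f">{clone.fasta_header()}\n{clone.dna}\n")


def truth_table(clones: Sequence[SimulatedClone]) -> pd.DataFrame:
    """Truth annotations as a DataFrame (one row per clone)."""
    return pd.DataFrame(
        {
            "identifier": [c.identifier for c in clones],
            "full_length": [c.full_length_truth for c in clones],
            "corruption": [c.corruption or "" for c in clones],
            "cdr3_protein": [c.cdr3_protein for c in clones],
            **{
                f"motif_{name}": [c.motif_truth.get(name, False) for c in clones]
                for name in (clones[0].motif_truth if clones else {})
            },
        }
    )


def simulate_selection(
    library: Sequence[SimulatedClone],
    weights: Mapping[str, float],
    n_out: int,
    seed: int,
) -> list[SimulatedClone]:
    """Biopanning as motif-weighted resampling with replacement.

    Each clone's weight is the product of ``weights[name]`` over the
    patterns it matches (truth annotations); unmatched patterns contribute
    a factor of 1.  Sampling is with replacement, so duplicates are
    expected and exercise downstream uniqueness logic.
    """
    for name, w in weights.items():
        if not (w >= 0 and np.isfinite(w)):
            raise ValueError(f"weight for {name!r} must be finite and >= 0, got {w}")
    raw = np.array(
        [
            float(
                np.prod([weights.get(n, 1.0) for n, hit in c.motif_truth.items() if hit])
            )
            for c in library
        ]
    )
    total = raw.sum()
    if total == 0:
        raise DegenerateWeightsError("all selection weights vanish on this library")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(library), size=n_out, replace=True, p=raw / total)
    return [library[int(i)] for i in picks]


def recover_enrichment_weight(
    selected_fraction: float, baseline_fraction: float
) -> float:
    """Invert the selection closed form: w = odds(selected) / odds(baseline)."""
    for frac in (selected_fraction, baseline_fraction):
        if not 0 < frac < 1:
            raise BoundaryError(f"fraction {frac} must lie strictly inside (0, 1)")
    return (selected_fraction / (1 - selected_fraction)) / (
        baseline_fraction / (1 - baseline_fraction)
    )
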