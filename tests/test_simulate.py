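"""Synthetic library generator: determinism, calibration, selection."""

import math
from fractions import Fraction

import numpy as np
import pytest

import cdr3kit as ck
from cdr3kit.errors import BoundaryError, ConfigError, DegenerateWeightsError


def binomial_3se(p, n):
    return 3 * math.sqrt(p * (1 - p) / n)


def test_fixed_seed_gives_byte_identical_fasta(tmp_path, cdr3_scheme, xbbxbx):
    paths = []
    for run in range(2):
        config = ck.SimulationConfig(scheme=cdr3_scheme, n_clones=50, seed=42)
        library = ck.sample_library(config, [xbbxbx])
        path = tmp_path / f"run{run}.fasta"
        ck.write_fasta(library, path)
        paths.append(path.read_bytes())
    assert paths[0] == paths[1]
    assert paths[0].startswith(b">clone000001|full_length=")


def test_different_seeds_give_different_libraries(cdr3_scheme):
    libs = [
        ck.sample_library(ck.SimulationConfig(scheme=cdr3_scheme, n_clones=30, seed=s))
        for s in (0, 1)
    ]
    assert [c.dna for c in libs[0]] != [c.dna for c in libs[1]]


def test_single_clone_fasta_is_reproducible(tmp_path, cdr3_scheme):
    blobs = []
    for run in range(2):
        config = ck.SimulationConfig(scheme=cdr3_scheme, n_clones=1, seed=3)
        path = tmp_path / f"one{run}.fasta"
        ck.write_fasta(ck.sample_library(config), path)
        blobs.append(path.read_bytes())
    assert blobs[0] == blobs[1]


def test_unsatisfiable_full_length_rate_is_rejected(cdr3_scheme):
    ceiling = float(ck.diversity(cdr3_scheme).stop_free_fraction_exact)
    with pytest.raises(ConfigError):
        ck.SimulationConfig(
            scheme=cdr3_scheme, n_clones=10, full_length_rate=ceiling + 0.01
        )


def test_uncorrupted_library_hits_the_stop_free_ceiling(big_clean_library):
    n = len(big_clean_library)
    p = float(Fraction(31, 32) ** 3)
    frac = sum(c.full_length_truth for c in big_clean_library) / n
    assert abs(frac - p) <= binomial_3se(p, n)


def test_motif_fraction_among_full_length_matches_theory(big_clean_library):
    full = [c for c in big_clean_library if c.full_length_truth]
    p = float(Fraction(10, 16) ** 3)
    frac = sum(c.motif_truth["XBBXBX"] for c in full) / len(full)
    assert abs(frac - p) <= binomial_3se(p, len(full))


def test_per_position_residue_frequencies_match_codon_distributions(
    big_clean_library, cdr3_scheme
):
    proteins = [
        c.cdr3_protein for c in big_clean_library if ck.STOP not in c.cdr3_protein
    ]
    n = len(proteins)
    table = ck.position_frequencies(proteins)
    for pos, codon in enumerate(cdr3_scheme.codons, start=1):
        dist = ck.codon_aa_distribution(codon, conditioned_on_sense=True)
        for residue in ck.AMINO_ACIDS:
            p = float(dist.exact[residue])
            if p * n < 5:
                continue
            observed = table.loc[residue, pos] / 100
            assert abs(observed - p) <= binomial_3se(p, n), (pos, residue)


def test_analyzer_full_length_rate_matches_corruption_target(cdr3_scheme, xbbxbx):
    config = ck.SimulationConfig(scheme=cdr3_scheme, n_clones=20_000, seed=9)
    library = ck.sample_library(config, [xbbxbx])
    records = [ck.CloneRecord(c.identifier, c.dna) for c in library]
    summary = ck.summarize(ck.analyze_clones(records, cdr3_scheme, [xbbxbx]), [xbbxbx])
    target = config.full_length_rate
    frac = summary.n_full_length / summary.n_selected
    assert abs(frac - target) <= binomial_3se(target, config.n_clones)
    # truth headers and analyzer agree clone by clone
    for sim, rec in zip(library, ck.analyze_clones(records, cdr3_scheme, [xbbxbx])):
        assert sim.full_length_truth == rec.full_length


def test_selection_enriches_to_the_closed_form_fraction(big_clean_library):
    w, n_out = 2.64, 5000
    p0 = sum(c.motif_truth["XBBXBX"] for c in big_clean_library) / len(big_clean_library)
    p1 = w * p0 / (w * p0 + (1 - p0))
    selected = ck.simulate_selection(big_clean_library, {"XBBXBX": w}, n_out, seed=17)
    frac = sum(c.motif_truth["XBBXBX"] for c in selected) / n_out
    assert abs(frac - p1) <= binomial_3se(p1, n_out)


def test_neutral_selection_preserves_library_fractions(big_clean_library):
    n_out = 5000
    p0 = sum(c.motif_truth["XBBXBX"] for c in big_clean_library) / len(big_clean_library)
    selected = ck.simulate_selection(big_clean_library, {"XBBXBX": 1.0}, n_out, seed=23)
    frac = sum(c.motif_truth["XBBXBX"] for c in selected) / n_out
    assert abs(frac - p0) <= binomial_3se(p0, n_out)


def test_zero_weight_excludes_all_matchers(big_clean_library):
    selected = ck.simulate_selection(
        big_clean_library[:2000], {"XBBXBX": 0.0}, 500, seed=5
    )
    assert not any(c.motif_truth["XBBXBX"] for c in selected)


def test_all_zero_weights_are_degenerate(big_clean_library):
    matchers = [c for c in big_clean_library if c.motif_truth["XBBXBX"]][:50]
    with pytest.raises(DegenerateWeightsError):
        ck.simulate_selection(matchers, {"XBBXBX": 0.0}, 10, seed=1)


def test_weight_recovery_closed_form_and_boundaries():
    assert ck.recover_enrichment_weight(0.46, 0.244) == pytest.approx(2.64, rel=0.01)
    assert ck.recover_enrichment_weight(0.3, 0.3) == 1.0
    with pytest.raises(BoundaryError):
        ck.recover_enrichment_weight(1.0, 0.5)
    with pytest.raises(BoundaryError):
        ck.recover_enrichment_weight(0.5, 0.0)


def test_weight_recovery_on_simulated_selection(big_clean_library):
    w, n_out = 2.64, 5000
    p0 = sum(c.motif_truth["XBBXBX"] for c in big_clean_library) / len(big_clean_library)
    selected = ck.simulate_selection(big_clean_library, {"XBBXBX": w}, n_out, seed=29)
    p1 = sum(c.motif_truth["XBBXBX"] for c in selected) / n_out
    estimate = ck.recover_enrichment_weight(p1, p0)
    assert abs(estimate - w) / w <= 0.10


def test_truth_table_shape_and_columns(cdr3_scheme, xbbxbx):
    config = ck.SimulationConfig(scheme=cdr3_scheme, n_clones=25, seed=8)
    library = ck.sample_library(config, [xbbxbx])
    table = ck.truth_table(library)
    assert len(table) == 25
    assert {"identifier", "full_length", "corruption", "motif_XBBXBX"} <= set(
        table.columns
    )
    corrupted = table[table.corruption != ""]
    assert set(corrupted.corruption) <= {
        "frameshift",
        "truncation",
        "stop_substitution",
    }
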