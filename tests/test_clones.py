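"""Clone analysis: CDR3 extraction, summaries, exact enrichment test."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

import cdr3kit as ck
from cdr3kit.clones import RESIDUE_ORDER
from cdr3kit.errors import DegenerateTableError, EmptySampleError, MotifLengthError

FR3 = "GACACGGCCCTGTATTACTGTGCAAGA"
FR4 = "TGGGGCCAAGGTACCCTGGTCACCGTCTCGAGAGGTGGAGGC"


def clone(window, ident="c1"):
    return ck.CloneRecord(identifier=ident, dna=FR3 + window + FR4)


def analyze(records, cdr3_scheme, patterns=()):
    return ck.analyze_clones(records, cdr3_scheme, patterns)


def test_window_between_anchors_is_extracted_and_translated(cdr3_scheme, xbbxbx):
    [rec] = analyze([clone("GGTCGTCGTCTGAAAGAT")], cdr3_scheme, [xbbxbx])
    assert rec.cdr3_dna == "GGTCGTCGTCTGAAAGAT"
    assert rec.cdr3_protein == "GRRLKD"
    assert rec.full_length
    assert rec.motif_matches == {"XBBXBX": True}


@pytest.mark.parametrize(
    "window",
    ["GGTCGTCGTCTGAAAGA", "GGTCGTTAGCTGAAAGAT"],  # 17 nt; in-frame stop
)
def test_frame_and_stop_violations_are_not_full_length(cdr3_scheme, window):
    [rec] = analyze([clone(window)], cdr3_scheme)
    assert not rec.full_length


def test_missing_anchor_flags_clone_without_raising(cdr3_scheme):
    records = [
        ck.CloneRecord(identifier="no_fr3", dna="GGTCGTCGTCTGAAAGAT" + FR4),
        ck.CloneRecord(identifier="no_fr4", dna=FR3 + "GGTCGTCGTCTGAAAGAT"),
    ]
    for rec in analyze(records, ck.xbbxbx_scheme()):
        assert rec.cdr3_dna is None or not rec.full_length
        assert not rec.full_length


def test_multiple_upstream_anchor_hits_warn_and_use_first(cdr3_scheme):
    dna = FR3 + "GGTCGTCGTCTGAAAGAT" + FR4 + FR3 + "AAATTTAAATTTAAATTT" + FR4
    with pytest.warns(UserWarning, match="multiple FR3 anchor"):
        window = ck.extract_cdr3(dna, FR3, FR4, 18)
    assert window == "GGTCGTCGTCTGAAAGAT"


def test_summary_counts_uniqueness_at_the_dna_level(cdr3_scheme, xbbxbx):
    windows = [
        "GGTCGTCGTCTGAAAGAT",  # GRRLKD
        "GGTCGTCGTCTGAAAGAT",  # duplicate DNA
        "GGCCGTCGTCTGAAAGAT",  # synonymous: also GRRLKD, distinct DNA
        "GCTGCTGCTGCTGCTGCT",  # AAAAAA, non-matcher
        "GGTCGTTAGCTGAAAGAT",  # in-frame stop, not full length
    ]
    records = analyze(
        [clone(w, f"c{i}") for i, w in enumerate(windows)], cdr3_scheme, [xbbxbx]
    )
    summary = ck.summarize(records, [xbbxbx])
    assert summary.n_selected == 5
    assert summary.n_full_length == 4
    assert summary.n_unique_dna == 3
    assert summary.n_unique_protein == 2
    assert summary.motif_counts["XBBXBX"] == 2
    assert summary.to_dict()["motifs"]["XBBXBX"]["percent"] == 66.7


def test_all_identical_sequences_collapse_to_one(cdr3_scheme):
    records = analyze([clone("GGTCGTCGTCTGAAAGAT", f"c{i}") for i in range(7)], cdr3_scheme)
    assert ck.summarize(records).n_unique_dna == 1


def test_summary_of_nothing_is_an_error():
    with pytest.raises(EmptySampleError):
        ck.summarize([])


def test_unique_percentage_convention_reproduces_sequencing_report():
    # 194 full-length clones, 189 distinct CDR3 DNA sequences
    assert ck.clones.round_half_up(100 * 189 / 194) == 97.4


def test_position_frequencies_of_a_single_sequence():
    table = ck.position_frequencies(["GRRLKD"])
    for pos, res in enumerate("GRRLKD", start=1):
        assert table.loc[res, pos] == 100.0
    assert list(table.index) == list(RESIDUE_ORDER)
    assert table.sum(axis=0).to_numpy() == pytest.approx([100.0] * 6, abs=0.2)


def test_position_frequency_columns_always_sum_to_100(cdr3_scheme):
    rng = np.random.default_rng(7)
    residues = np.array(list(ck.AMINO_ACIDS))
    cdr3s = ["".join(rng.choice(residues, 6)) for _ in range(321)]
    table = ck.position_frequencies(cdr3s)
    assert table.sum(axis=0).to_numpy() == pytest.approx([100.0] * 6, abs=0.2)


def test_position_frequencies_reject_mixed_lengths():
    with pytest.raises(MotifLengthError):
        ck.position_frequencies(["GRRLKD", "GRRLK"])


def oracle_fisher(a, b, c, d):
    """Independent two-sided oracle: enumerate every table with the observed
    margins, computing each probability from factorials."""
    f = math.factorial
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d

    def prob(k):
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
            return Fraction(0)
        return Fraction(
            f(r1) * f(r2) * f(c1) * f(n - c1),
            f(n) * f(k) * f(r1 - k) * f(c1 - k) * f(r2 - (c1 - k)),
        )

    observed = prob(a)
    return sum(p for k in range(0, c1 + 1) if (p := prob(k)) <= observed)


def test_fisher_agrees_exactly_with_enumeration_oracle_on_small_tables():
    rng = np.random.default_rng(11)
    tables = [tuple(rng.integers(0, 16, 4)) for _ in range(60)]
    tables += [(31, 36, 44, 145), (1, 0, 0, 1), (5, 5, 5, 5)]
    for a, b, c, d in tables:
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            continue
        ours = ck.fisher_exact_two_sided(a, b, c, d)
        assert ours == oracle_fisher(a, b, c, d)
        # independent float route
        assert float(ours) == pytest.approx(
            scipy_fisher([[a, b], [c, d]])[1], rel=1e-6
        )


def test_enrichment_of_selected_clones_is_significant():
    result = ck.enrichment_test((31, 67), (44, 189))
    assert result.p_value < 0.01
    assert result.odds_ratio > 1
    chi2 = ck.enrichment_test((31, 67), (44, 189), method="chi2")
    assert chi2.p_value < 0.01


def test_identical_proportions_give_p_of_one():
    result = ck.enrichment_test((10, 100), (10, 100))
    assert result.p_value_exact == 1


def test_zero_margin_table_is_degenerate():
    with pytest.raises(DegenerateTableError):
        ck.enrichment_test((0, 10), (0, 20))
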