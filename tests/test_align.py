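"""Alignment engine: brute-force oracle agreement and MSA contracts."""

import math

import numpy as np
import pytest
from oracles import enumerate_best_score

from seedquant.align import (AMINO_ACIDS, Alignment, SequenceRecord,
                             conservation_classes, global_align,
                             identity_table, overall_homology,
                             percent_identity, progressive_msa,
                             substitution_table)


def _rec(name, seq):
    return SequenceRecord(id=name, species=name, residues=seq)


def test_identical_sequences_align_without_gaps():
    aln, score = global_align(_rec("a", "ACDE"), _rec("b", "ACDE"),
                              table=identity_table(), gap_open=-2.0,
                              gap_extend=-2.0)
    assert aln.rows == ("ACDE", "ACDE")
    assert score == 4.0


def test_alignment_against_empty_is_one_gap_run():
    gap_open, gap_extend = -2.0, -1.0
    # one residue against four: three positions must sit in one gap run
    aln, score = global_align(_rec("a", "ACDE"), _rec("b", "A"),
                              table=identity_table(), gap_open=gap_open,
                              gap_extend=gap_extend)
    assert score == 1.0 + gap_open + 2 * gap_extend
    assert aln.rows[1].count("-") == 3


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        _rec("a", "")


def test_unknown_residue_rejected_but_x_allowed():
    with pytest.raises(ValueError):
        _rec("a", "ACZ")
    rec = _rec("a", "AXC")
    aln, score = global_align(rec, _rec("b", "AXC"), table=identity_table())
    assert aln.rows == ("AXC", "AXC")


def test_scores_match_exhaustive_enumeration(rng):
    """Gotoh DP equals brute-force enumeration on 100 random peptide pairs."""
    blosum = substitution_table()
    from seedquant.align import _INDEX

    def s(x, y):
        return blosum[_INDEX[x], _INDEX[y]]

    for k in range(100):
        la, lb = rng.integers(1, 7, size=2)
        a = "".join(rng.choice(list(AMINO_ACIDS), la))
        b = "".join(rng.choice(list(AMINO_ACIDS), lb))
        go, ge = float(-rng.integers(2, 12)), float(-rng.integers(1, 4))
        _, dp_score = global_align(_rec("a", a), _rec("b", b),
                                   gap_open=go, gap_extend=ge)
        brute = enumerate_best_score(a, b, s, go, ge)
        assert dp_score == pytest.approx(brute, abs=1e-9), (a, b, go, ge)


def test_score_symmetric_in_arguments(rng):
    for _ in range(25):
        a = "".join(rng.choice(list(AMINO_ACIDS), rng.integers(1, 10)))
        b = "".join(rng.choice(list(AMINO_ACIDS), rng.integers(1, 10)))
        _, s_ab = global_align(_rec("a", a), _rec("b", b))
        _, s_ba = global_align(_rec("b", b), _rec("a", a))
        assert s_ab == pytest.approx(s_ba, abs=1e-9)


# --------------------------------------------------------------------------
# Progressive MSA

def test_msa_of_identical_sequences_has_no_gaps():
    seqs = [_rec(f"s{i}", "MKFFVDE") for i in range(4)]
    aln = progressive_msa(seqs)
    assert all("-" not in row for row in aln.rows)
    assert aln.column_count == 7


def test_msa_of_two_reduces_to_pairwise():
    a, b = _rec("a", "MKFFVDEACD"), _rec("b", "MKFVDEACD")
    pair, _ = global_align(a, b)
    aln = progressive_msa([a, b])
    assert aln.rows == pair.rows


def test_msa_degapping_recovers_inputs(rng, simulated_families):
    # structured families plus a random ragged family
    fam, aln = simulated_families[0]
    for rec in fam.records:
        assert aln.row(rec.id).replace("-", "") == rec.residues
    ragged = [_rec(f"r{i}",
                   "".join(rng.choice(list(AMINO_ACIDS),
                                      rng.integers(8, 20))))
              for i in range(5)]
    aln2 = progressive_msa(ragged)
    for rec in ragged:
        assert aln2.row(rec.id).replace("-", "") == rec.residues


def test_msa_on_indel_free_family_preserves_columns(simulated_families):
    for fam, aln in simulated_families[:10]:
        for rec in fam.records:
            assert aln.row(rec.id) == rec.residues


# --------------------------------------------------------------------------
# Identity and homology

def test_percent_identity_examples():
    assert percent_identity("ACDE", "ACDE") == 100.0
    assert math.isnan(percent_identity("AC--", "--DE"))
    # 8 columns: 6 matches, 1 mismatch, 1 gap column -> 600/7
    assert percent_identity("AAAAAAC-", "AAAAAAAA") == pytest.approx(600 / 7)


def test_percent_identity_is_symmetric_and_bounded(rng):
    for _ in range(30):
        n = int(rng.integers(2, 12))
        mk = lambda: "".join(rng.choice(list(AMINO_ACIDS + "-"), n))
        x, y = mk(), mk()
        pij, pji = percent_identity(x, y), percent_identity(y, x)
        if math.isnan(pij):
            assert math.isnan(pji)
        else:
            assert pij == pji and 0.0 <= pij <= 100.0


def test_overall_homology_reductions():
    aln = Alignment(ids=("a", "b"), rows=("ACDE", "ACDG"))
    summary = overall_homology(aln)
    assert summary.min_pairwise_identity == percent_identity("ACDE", "ACDG")
    same = Alignment(ids=("a", "b", "c"), rows=("ACDE",) * 3)
    s2 = overall_homology(same)
    assert s2.min_pairwise_identity == 100.0
    assert s2.conserved_column_fraction == 1.0


def test_overall_homology_matches_brute_force_min(rng):
    rows = tuple("".join(rng.choice(list("ACDE-"), 12)) for _ in range(5))
    rows = tuple(r if r.strip("-") else "A" * 12 for r in rows)
    aln = Alignment(ids=tuple("abcde"), rows=rows)
    pairs = [percent_identity(rows[i], rows[j])
             for i in range(5) for j in range(i + 1, 5)]
    finite = [p for p in pairs if not math.isnan(p)]
    assert overall_homology(aln).min_pairwise_identity == min(finite)


def test_adding_a_row_never_raises_min_identity(rng):
    rows = ["".join(rng.choice(list("ACDEFG"), 15)) for _ in range(6)]
    sub = Alignment(ids=tuple("abcde"), rows=tuple(rows[:5]))
    full = Alignment(ids=tuple("abcdef"), rows=tuple(rows))
    assert (overall_homology(full).min_pairwise_identity
            <= overall_homology(sub).min_pairwise_identity)


# --------------------------------------------------------------------------
# Conservation classes

def test_conservation_class_boundaries():
    aln = Alignment(
        ids=tuple("abcd"),
        rows=("AAAA", "AAAB", "AABB", "ABBC"),
    )
    # columns: 4/4 A -> full; col2: AAAB 3/4 = 0.75 -> mid (boundary down);
    # col3: A A B B 2/4 = 0.5 -> low; col4: A B B C 2/4 = 0.5 -> low
    assert conservation_classes(aln) == ["full", "mid", "low", "low"]


def test_conservation_five_rows_eighty_percent_is_high():
    aln = Alignment(ids=tuple("abcde"), rows=("A", "A", "A", "A", "B"))
    assert conservation_classes(aln) == ["high"]


def test_conservation_gaps_count_against_similarity():
    aln = Alignment(ids=tuple("abcd"), rows=("A", "A", "-", "-"))
    assert conservation_classes(aln) == ["low"]
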