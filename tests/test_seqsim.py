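"""Sequence-family generator: divergence structure and planted sites."""

import numpy as np
import pytest

from seedquant.align import AMINO_ACIDS, percent_identity
from seedquant.seqsim import (DEFAULT_GROUPS, PlantedSite, SequenceSimParams,
                              simulate_sequence_family)
from seedquant.sites import residue_property


def test_zero_branch_lengths_give_identical_sequences():
    params = SequenceSimParams(
        tree_spec="((mouse:0,cat:0):0,(cattle:0,(goat:0,camel:0):0):0);",
        planted_sites=(), groups={}, rng_seed=5)
    fam = simulate_sequence_family(params)
    seqs = {r.residues for r in fam.records}
    assert len(seqs) == 1
    for a in fam.records:
        for b in fam.records:
            assert percent_identity(a.residues, b.residues) == 100.0


def test_sequences_use_amino_acid_alphabet():
    fam = simulate_sequence_family(SequenceSimParams(rng_seed=1))
    for rec in fam.records:
        assert set(rec.residues) <= set(AMINO_ACIDS)
        assert len(rec.residues) == 130


def test_generator_is_deterministic():
    a = simulate_sequence_family(SequenceSimParams(rng_seed=9))
    b = simulate_sequence_family(SequenceSimParams(rng_seed=9))
    assert [r.residues for r in a.records] == [r.residues for r in b.records]


def test_planted_sites_carry_exact_pattern():
    fam = simulate_sequence_family(SequenceSimParams(rng_seed=2))
    high = DEFAULT_GROUPS["high"]
    low = DEFAULT_GROUPS["low"]
    col48 = {sp: fam.record(sp).residues[47] for sp in high + low}
    assert all(col48[sp] in "QI" for sp in high)
    assert all(col48[sp] == "K" for sp in low)
    col125 = {sp: fam.record(sp).residues[124] for sp in high + low}
    assert all(residue_property(col125[sp]) == "acidic" for sp in high)
    assert all(col125[sp] == "A" for sp in low)


def test_identity_decreases_with_tree_path_length():
    """Mean pairwise identity over seeds follows the tree's path lengths.

    Checked on the unconditioned substitution process
    (``clean_background=False``): the clean-background rejection step
    deliberately suppresses patterns where the high-activity clade
    jointly diverged, which perturbs cross-clade identities by a
    fraction of a percent.
    """
    pair_paths = {  # path lengths on the default tree
        ("cat", "mouse"): 0.06,
        ("cattle", "goat"): 0.16,
        ("cat", "human"): 0.20,
        ("cat", "cattle"): 0.28,
    }
    sums = {p: 0.0 for p in pair_paths}
    n_seeds = 25
    for seed in range(n_seeds):
        fam = simulate_sequence_family(
            SequenceSimParams(rng_seed=seed, clean_background=False))
        for (a, b) in pair_paths:
            sums[(a, b)] += percent_identity(fam.record(a).residues,
                                             fam.record(b).residues)
    means = [sums[p] / n_seeds for p in pair_paths]  # ordered by path length
    assert all(x > y for x, y in zip(means, means[1:]))


def test_unrealizable_planted_pattern_rejected():
    with pytest.raises(ValueError):
        SequenceSimParams(planted_sites=(
            PlantedSite(10, {"high": "basic", "low": "K"}),))  # overlap
    with pytest.raises(ValueError):
        SequenceSimParams(planted_sites=(
            PlantedSite(10, {"high": "", "low": "K"}),))
    with pytest.raises(ValueError):
        SequenceSimParams(planted_sites=(
            PlantedSite(999, {"high": "DE", "low": "K"}),))


def test_negative_branch_length_rejected():
    params = SequenceSimParams(
        tree_spec="(mouse:-0.1,cat:0.1);", planted_sites=(),
        groups={}, rng_seed=0)
    with pytest.raises(ValueError):
        simulate_sequence_family(params)


def test_group_member_missing_from_tree_rejected():
    params = SequenceSimParams(tree_spec="(mouse:0.1,cat:0.1);",
                               planted_sites=(), rng_seed=0)
    with pytest.raises(ValueError):
        simulate_sequence_family(params)
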