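"""Alignment layer: pairwise affine oracle, translation, profiles, trimming."""
import itertools

import numpy as np
import pytest

from sparsephylo.alignment import (AlignmentError, AlignmentProfile,
                                   ScoringScheme, low_occupancy_columns,
                                   pairwise_affine_align, profile_merge,
                                   translation_align, trim_ends)
from sparsephylo.formats import SequenceRecord


def brute_force_best_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Enumerate every global alignment (pairs of gapped strings) and score
    it with gap runs costing open + L*extend.  Exponential; lengths <= 8."""

    def score_alignment(ga: str, gb: str) -> float:
        s = 0.0
        for run_in in (ga, gb):
            i = 0
            while i < len(run_in):
                if run_in[i] == "-":
                    j = i
                    while j < len(run_in) and run_in[j] == "-":
                        j += 1
                    s -= scheme.gap_open + (j - i) * scheme.gap_extend
                    i = j
                else:
                    i += 1
        for x, y in zip(ga, gb):
            if x != "-" and y != "-":
                s += scheme.score(x, y)
        return s

    best = float("-inf")
    n, m = len(a), len(b)

    def rec(i, j, ga, gb):
        nonlocal best
        if i == n and j == m:
            best = max(best, score_alignment(ga, gb))
            return
        if i < n:
            rec(i + 1, j, ga + a[i], gb + "-")
        if j < m:
            rec(i, j + 1, ga + "-", gb + b[j])
        if i < n and j < m:
            rec(i + 1, j + 1, ga + a[i], gb + b[j])

    rec(0, 0, "", "")
    return best


NT = ScoringScheme.nucleotide(gap_open=5.0, gap_extend=2.0)


def test_identity_alignment_scores_blosum_diagonal():
    aligned_a, aligned_b, score = pairwise_affine_align("ACDE", "ACDE")
    assert aligned_a == aligned_b == "ACDE"
    bl = ScoringScheme().matrix
    assert score == pytest.approx(sum(bl[(c, c)] for c in "ACDE"))


def test_single_residue_vs_empty_pays_open_plus_extend():
    a, b, score = pairwise_affine_align("A", "", ScoringScheme())
    assert (a, b) == ("A", "-")
    assert score == pytest.approx(-(12 + 3))


@pytest.mark.parametrize("seed", range(6))
def test_pairwise_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    chars = np.array(list("ACGT"))
    a = "".join(chars[rng.integers(0, 4, rng.integers(2, 7))])
    b = "".join(chars[rng.integers(0, 4, rng.integers(2, 7))])
    ga, gb, score = pairwise_affine_align(a, b, NT)
    assert score == pytest.approx(brute_force_best_score(a, b, NT))
    assert ga.replace("-", "") == a and gb.replace("-", "") == b


def test_pairwise_score_symmetric():
    rng = np.random.default_rng(10)
    chars = np.array(list("ACGT"))
    for _ in range(5):
        a = "".join(chars[rng.integers(0, 4, 6)])
        b = "".join(chars[rng.integers(0, 4, 8)])
        _, _, s1 = pairwise_affine_align(a, b, NT)
        _, _, s2 = pairwise_affine_align(b, a, NT)
        assert s1 == pytest.approx(s2)


def test_symbol_outside_alphabet_errors():
    with pytest.raises(AlignmentError):
        pairwise_affine_align("AXXA", "ACGT", NT)


# --------------------------------------------------------------- translation

def r(t, s):
    return SequenceRecord(t, "gene", s)


def test_translation_identity_and_gap_expansion():
    recs = [r("a", "ATGAAA"), r("b", "ATGAAA")]
    out, rejected = translation_align(recs)
    assert not rejected
    assert all(x.residues == "ATGAAA" for x in out)

    recs = [r("a", "ATGAAGTTT"), r("b", "ATGTTT")]
    out, rejected = translation_align(recs)
    assert not rejected
    by = {x.taxon_label: x.residues for x in out}
    assert len(by["a"]) == len(by["b"]) == 9
    assert "---" in by["b"]  # one aa gap -> 3 nt gaps


def test_translation_degap_recovers_inputs():
    rng = np.random.default_rng(3)
    codons = ["ATG", "AAA", "GGG", "TTT", "CCC", "GAT", "TGC"]
    recs = []
    for i in range(4):
        k = int(rng.integers(3, 7))
        recs.append(r(f"t{i}", "".join(rng.choice(codons, k))))
    out, rejected = translation_align(recs)
    assert not rejected
    originals = {x.taxon_label: x.residues for x in recs}
    for x in out:
        assert x.residues.replace("-", "") == originals[x.taxon_label]


def test_translation_rejects_all_frame_stops():
    recs = [r("ok", "ATGAAAGGG"), r("bad", "TAAATAAATAAATAAATAAA")]
    out, rejected = translation_align(recs)
    assert rejected and rejected[0][0] == "bad"
    assert {x.taxon_label for x in out} == {"ok"}


# ------------------------------------------------------------------ profiles

def test_profile_merge_of_singletons_equals_pairwise():
    a, b = "ACGTACGT", "ACGACGT"
    p = profile_merge(AlignmentProfile([r("x", a)]), AlignmentProfile([r("y", b)]), NT)
    ga, gb, _ = pairwise_affine_align(a, b, NT)
    by = {x.taxon_label: x.residues for x in p.member_records}
    assert by["x"] == ga and by["y"] == gb


def test_profile_merge_preserves_within_profile_identity():
    p1 = AlignmentProfile([r("a", "ACGT-ACGT"), r("b", "ACGTTACGT")])
    p2 = AlignmentProfile([r("c", "ACGTACG")])
    merged = profile_merge(p1, p2, NT)
    by = {x.taxon_label: x.residues for x in merged.member_records}

    def pairwise_identity(x, y):
        return [(i, j) for i, j in zip(x, y) if i != "-" and j != "-"]

    assert pairwise_identity(by["a"], by["b"]) == pairwise_identity("ACGT-ACGT", "ACGTTACGT")


def test_profile_merge_empty_errors():
    with pytest.raises(AlignmentError):
        AlignmentProfile([])


def test_progressive_alignment_of_identical_sequences_has_no_gaps():
    recs = [r(f"t{i}", "ACGTACGTAA") for i in range(5)]
    p = AlignmentProfile.from_sequences(recs, NT)
    assert all("-" not in x.residues for x in p.member_records)
    assert p.width == 10


# ------------------------------------------------------------------ trimming

def test_trim_ends_examples_and_idempotence():
    full = AlignmentProfile([r("a", "ACGTACGTAC"), r("b", "ACGTACGTAC")])
    assert trim_ends(full).width == 10  # full occupancy -> unchanged

    sparse = AlignmentProfile(
        [r(f"t{i}", ("--" if i else "AC") + "GTACGTAC") for i in range(10)])
    trimmed = trim_ends(sparse, 0.5)
    assert trimmed.width == 8
    again = trim_ends(trimmed, 0.5)
    assert again.width == trimmed.width

    allgap = AlignmentProfile([r("a", "--"), r("b", "--")])
    with pytest.raises(AlignmentError):
        trim_ends(allgap, 0.5)


def test_low_occupancy_columns_flagged_for_review():
    p = AlignmentProfile([r("a", "A---A"), r("b", "AAA-A"),
                          r("c", "AAA-A"), r("d", "AAA-A")])
    assert low_occupancy_columns(p, 0.25) == [3]
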