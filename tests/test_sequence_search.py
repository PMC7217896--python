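"""Profile construction, local alignment and score statistics."""

import math

import numpy as np
import pytest

from oracles import bisect_lambda, naive_local_score

from hspscan.domain_models import DOMAIN_ALIGNMENTS, DOMAIN_CONSENSUS
from hspscan.io_formats import AMINO_ACIDS, SequenceRecord
from hspscan.sequence_search import (AA_INDEX, ScoreStatistics,
                                     blosum62_matrix, build_pssm,
                                     calibrate_statistics,
                                     filter_homology_hits,
                                     nucleotide_matrix, profile_statistics,
                                     scan_profile, smith_waterman)


def _random_protein(rng, n):
    return "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, n))


# ---------------------------------------------------------------------------
# PSSM construction
# ---------------------------------------------------------------------------

def test_pssm_invariant_column_zero_pseudocount():
    # a column of pure A against uniform background scores
    # 2*log2(1/0.05) = 8.64 half-bits, rounded to 9; absent residues are
    # floored rather than -inf
    prof = build_pssm(["A", "A", "A"], pseudocount_weight=0.0,
                      score_floor=-32.0)
    assert prof.scores[0, AA_INDEX["A"]] == round(2 * math.log2(20))
    assert (prof.scores[0, np.arange(20) != AA_INDEX["A"]] == -32.0).all()


def test_pssm_background_equal_frequencies_scores_zero():
    # 20 rows, one of each residue: observed frequency = uniform background
    rows = list(AMINO_ACIDS)
    prof = build_pssm(rows, pseudocount_weight=0.0)
    assert (prof.scores == 0).all()


def test_pssm_pseudocounts_shrink_scores_toward_zero():
    rows = ["AC", "AC", "AD"]
    light = build_pssm(rows, pseudocount_weight=0.5)
    heavy = build_pssm(rows, pseudocount_weight=5.0)
    assert (np.abs(heavy.scores) <= np.abs(light.scores)).all()


def test_pssm_errors_and_gap_columns():
    with pytest.raises(ValueError):
        build_pssm(["A"])                          # fewer than two rows
    with pytest.raises(ValueError):
        build_pssm(["", ""])                       # zero columns
    prof = build_pssm(["A-C", "A-C"])              # all-gap column dropped
    assert prof.length == 2


# ---------------------------------------------------------------------------
# Profile scanning
# ---------------------------------------------------------------------------

def test_scan_consensus_attains_ungapped_offset_maximum():
    """An exact consensus in random flanks scores the per-position maxima
    sum, equal to an exhaustive enumeration over all ungapped offsets."""
    rng = np.random.default_rng(21)
    for dom in ("pfam00011", "pfam00012"):
        prof = build_pssm(DOMAIN_ALIGNMENTS[dom], domain_id=dom)
        consensus = DOMAIN_CONSENSUS[dom]
        left, right = _random_protein(rng, 40), _random_protein(rng, 40)
        protein = SequenceRecord("p", left + consensus + right)
        hits = scan_profile(protein, prof)
        assert hits, "planted consensus not found"
        best = hits[0]
        # oracle: best ungapped score over every offset of the profile
        enc = [AA_INDEX[c] for c in protein.sequence]
        L = prof.length
        oracle = max(
            sum(prof.scores[i, enc[off + i]] for i in range(L))
            for off in range(len(enc) - L + 1))
        assert best.raw_score == pytest.approx(oracle)
        assert best.raw_score == pytest.approx(prof.max_score())
        assert best.query_start <= len(left) + 1
        assert best.query_end >= len(left) + len(consensus)


def test_scan_beats_composition_matched_shuffles():
    rng = np.random.default_rng(22)
    prof = build_pssm(DOMAIN_ALIGNMENTS["pfam00183"], domain_id="pfam00183")
    consensus = DOMAIN_CONSENSUS["pfam00183"]
    flanks = (_random_protein(rng, 30), _random_protein(rng, 30))
    planted = scan_profile(
        SequenceRecord("p", flanks[0] + consensus + flanks[1]), prof)
    planted_score = planted[0].raw_score
    chars = np.array(list(consensus))
    for _ in range(200):
        rng.shuffle(chars)
        shuffled = scan_profile(
            SequenceRecord("s", flanks[0] + "".join(chars) + flanks[1]), prof)
        score = shuffled[0].raw_score if shuffled else 0.0
        assert score < planted_score


def test_scan_short_protein_returns_empty():
    prof = build_pssm(DOMAIN_ALIGNMENTS["pfam00011"])
    assert scan_profile(SequenceRecord("p", "MAV"), prof) == []


def test_profile_lambda_near_half_bit_units():
    prof = build_pssm(DOMAIN_ALIGNMENTS["pfam00226"])
    stats = profile_statistics(prof)
    # half-bit log-odds imply lambda close to ln(2)/2
    assert stats.lam == pytest.approx(math.log(2) / 2, rel=0.2)


# ---------------------------------------------------------------------------
# Smith-Waterman
# ---------------------------------------------------------------------------

def test_self_alignment_scores_diagonal_sum():
    seq = "MKVLHEWDNATQRC"
    matrix = blosum62_matrix()
    res = smith_waterman(SequenceRecord("a", seq), SequenceRecord("b", seq))
    expected = sum(matrix[AA_INDEX[c], AA_INDEX[c]] for c in seq)
    assert res.raw_score == pytest.approx(expected)
    assert res.identity_pct == 100.0
    assert res.query_span == (1, len(seq)) and res.subject_span == (1, len(seq))


def test_no_positive_pair_scores_zero():
    a = SequenceRecord("a", "AAAA", "nt")
    b = SequenceRecord("b", "TTTT", "nt")
    res = smith_waterman(a, b, nucleotide_matrix())
    assert res.raw_score == 0.0 and res.aligned_cols == 0


def test_empty_sequence_flagged():
    res = smith_waterman(SequenceRecord("a", "", alphabet="aa"),
                         SequenceRecord("b", "MKV"))
    assert res.raw_score == 0.0 and math.isnan(res.identity_pct)


def test_scores_match_full_dp_oracle():
    """100 random pairs: affine Gotoh kernel equals the gap-length-scanning
    full DP, exactly."""
    rng = np.random.default_rng(42)
    matrix = blosum62_matrix()
    for _ in range(100):
        a = _random_protein(rng, int(rng.integers(10, 61)))
        b = _random_protein(rng, int(rng.integers(10, 61)))
        fast = smith_waterman(SequenceRecord("a", a), SequenceRecord("b", b),
                              gap_open=11, gap_extend=1).raw_score
        slow = naive_local_score(a, b, matrix, 11, 1)
        assert fast == pytest.approx(slow)


def test_score_symmetric_for_symmetric_matrix():
    rng = np.random.default_rng(13)
    for _ in range(10):
        a = SequenceRecord("a", _random_protein(rng, 40))
        b = SequenceRecord("b", _random_protein(rng, 50))
        assert smith_waterman(a, b).raw_score == \
            pytest.approx(smith_waterman(b, a).raw_score)


def test_scores_match_biopython_local_aligner():
    from Bio import Align
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12.0    # open + extend for the first residue
    aligner.extend_gap_score = -1.0
    rng = np.random.default_rng(77)
    for _ in range(15):
        a, b = _random_protein(rng, 45), _random_protein(rng, 55)
        ours = smith_waterman(SequenceRecord("a", a), SequenceRecord("b", b),
                              gap_open=11, gap_extend=1).raw_score
        assert ours == pytest.approx(aligner.score(a, b))


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics
# ---------------------------------------------------------------------------

def test_lambda_matches_bisection_oracle():
    m = np.full((4, 4), -1.0)
    np.fill_diagonal(m, 1.0)
    stats = calibrate_statistics(m, np.full(4, 0.25))
    values = np.array([-1, 1])
    probs = np.array([0.75, 0.25])
    assert abs(stats.lam - bisect_lambda(values, probs)) < 1e-6
    assert stats.lam == pytest.approx(math.log(3.0), abs=1e-9)


def test_lambda_scaling_inverse_to_matrix_scale():
    m = np.full((4, 4), -3.0)
    np.fill_diagonal(m, 2.0)
    bg = np.full(4, 0.25)
    base = calibrate_statistics(m, bg)
    scaled = calibrate_statistics(2.0 * m, bg)
    assert scaled.lam == pytest.approx(base.lam / 2.0, rel=1e-6)


def test_blosum62_calibration_matches_published_constants():
    """Sanity anchor: BLOSUM62 under standard composition gives the
    textbook ungapped lambda ~0.3176 and K ~0.134."""
    rob = {"A": .07805, "C": .01925, "D": .05364, "E": .06295, "F": .03856,
           "G": .07377, "H": .02199, "I": .05142, "K": .05744, "L": .09019,
           "M": .02243, "N": .04487, "P": .05203, "Q": .04264, "R": .05129,
           "S": .07120, "T": .05841, "V": .06441, "W": .01330, "Y": .03216}
    bg = np.array([rob[a] for a in AMINO_ACIDS])
    stats = calibrate_statistics(blosum62_matrix()[:20, :20], bg / bg.sum())
    assert stats.lam == pytest.approx(0.3176, abs=2e-3)
    assert stats.K == pytest.approx(0.134, abs=5e-3)


def test_non_negative_expected_score_rejected():
    m = np.full((4, 4), 1.0)
    with pytest.raises(ValueError):
        calibrate_statistics(m, np.full(4, 0.25))
    m2 = np.full((4, 4), -1.0)
    np.fill_diagonal(m2, 9.0)       # expected score positive
    with pytest.raises(ValueError, match="expected"):
        calibrate_statistics(m2, np.full(4, 0.25))


def test_evalue_monotone_in_score_and_linear_in_search_space():
    stats = ScoreStatistics(lam=0.3, K=0.1)
    scores = np.arange(10, 100, 7)
    e = [stats.e_value(s, 1e6) for s in scores]
    assert all(e[i] > e[i + 1] for i in range(len(e) - 1))
    assert stats.e_value(50, 2e6) == pytest.approx(2 * stats.e_value(50, 1e6))


def test_homology_filter_strictness():
    def hit(e, bit):
        from hspscan.sequence_search import AlignmentResult
        return AlignmentResult("q", "s", 0, bit, e, 50.0, 10, (1, 5), (1, 5))
    kept = filter_homology_hits(
        [hit(1e-5, 250.0), hit(1e-5, 100.0), hit(1e-3, 300.0)])
    assert len(kept) == 1 and kept[0].bit_score == 250.0
    assert filter_homology_hits([]) == []
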